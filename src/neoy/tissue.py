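"""Tissue-specificity scoring (tau) and the permutation overlap test.

tau = sum_i (1 - x_i / x_max) / (N - 1) over N tissues; genes with
tau above the threshold are tissue-biased and assigned their two
highest-expression tissues.  Enrichment/depletion of tissue-biased genes
among focal (neo-X-biased) genes is assessed by repeated double draws
without replacement, with the expected count the median of the null and a
two-sided percentile p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def compute_tau(expression: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Per-gene tau and top-2 tissue assignment.

    ``expression`` is genes x tissues (RPKM-like, non-negative).  All-zero
    genes have undefined tau and are dropped.  ``top_tissues`` is empty
    unless tau exceeds the threshold.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    if (expression.values < 0).any():
        raise ValueError("expression must be non-negative")
    n = expression.shape[1]
    rows = []
    for gene, x in expression.iterrows():
        xmax = x.max()
        if xmax == 0:
            log.warning("gene %s all-zero: tau undefined, dropped", gene)
            continue
        tau = float((1.0 - x / xmax).sum() / (n - 1))
        top: tuple[str, ...] = ()
        if tau > threshold:
            top = tuple(x.sort_values(ascending=False).index[:2])
        rows.append((gene, tau, top))
    return pd.DataFrame(rows, columns=["gene", "tau", "top_tissues"])


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    p: float
    signed_stat: float
    null_mean: float
    reps: int


def permutation_overlap_test(n_tissue_biased: int, n_focal: int,
                             universe_chr3: int, universe_filtered: int,
                             observed: int, reps: int = 100_000, seed: int = 0,
                             universe_shared: int | None = None) -> EnrichmentResult:
    """Double-draw permutation test of tissue-biased / focal gene overlap.

    Per replicate, ``n_tissue_biased`` genes are drawn without replacement
    from the chromosome-wide universe and ``n_focal`` genes from the
    filtered universe; the overlap is counted on the ``universe_shared``
    genes common to both universes (defaulting to the smaller universe,
    i.e. nested sets).  The expected count is the median of the null, the
    p-value a two-sided percentile (2 x min tail, capped at 1), and the
    signed display statistic sign(obs - exp) x (obs - exp)^2 / max(exp, 1).
    """
    if n_tissue_biased > universe_chr3 or n_focal > universe_filtered:
        raise ValueError("draw size exceeds its universe")
    if universe_shared is None:
        universe_shared = min(universe_chr3, universe_filtered)
    if observed > min(n_tissue_biased, n_focal):
        raise ValueError("observed overlap exceeds the smaller draw")
    if reps < 1000:
        log.warning("reps < 1000: percentile p-value will be unstable")
    rng = np.random.default_rng(seed)
    # genes 0..universe_shared-1 lie in both universes
    null = np.empty(reps, dtype=np.int64)
    shared = universe_shared
    for i in range(reps):
        a = rng.choice(universe_chr3, size=n_tissue_biased, replace=False)
        b = rng.choice(universe_filtered, size=n_focal, replace=False)
        null[i] = np.intersect1d(a[a < shared], b[b < shared]).size
    expected = float(np.median(null))
    ge = float(np.mean(null >= observed))
    le = float(np.mean(null <= observed))
    p = min(1.0, 2.0 * min(ge, le))
    delta = observed - expected
    sign = 0.0 if delta == 0 else (1.0 if delta > 0 else -1.0)
    signed = sign * delta * delta / max(expected, 1.0)
    return EnrichmentResult(observed=observed, expected=expected, p=p,
                            signed_stat=signed, null_mean=float(null.mean()),
                            reps=reps)


def enrichment_matrix(results: dict[tuple[str, str], EnrichmentResult]) -> pd.DataFrame:
    """(group, tissue) results as a heatmap-ready signed-statistic matrix."""
    groups = sorted({g for g, _ in results})
    tissues = sorted({t for _, t in results})
    mat = pd.DataFrame(index=groups, columns=tissues, dtype=float)
    for (g, t), r in results.items():
        mat.loc[g, t] = r.signed_stat
    return mat
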