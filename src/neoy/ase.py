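"""Allele-specific expression with DNA-based reference-bias correction.

The RNA-seq neo-X/neo-Y fold difference of each gene is divided by the
DNA-seq fold difference, cancelling residual mapping bias; per-gene
significance comes from a two-sided Fisher's exact test on the 2x2
RNA-vs-DNA count table with Benjamini-Hochberg control, and the
chromosome-level excess of neo-X- over neo-Y-biased genes from an exact
binomial test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from neoy.config import SimulationConfig
from neoy.simulate import simulate_allele_counts

log = logging.getLogger(__name__)

MIN_READS = 5  # genes with fewer than 5 reads in both alleles are removed


def corrected_fold_difference(rna_x: int, rna_y: int, dna_x: int, dna_y: int) -> float:
    """(rna_x/rna_y) / (dna_x/dna_y), with Haldane-Anscombe +0.5 on zeros.

    The continuity correction applies to the fold computation only; tests
    use the raw counts.  An all-zero record is undefined.
    """
    cells = (rna_x, rna_y, dna_x, dna_y)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if all(c == 0 for c in cells):
        raise ValueError("all-zero record: fold undefined")
    if any(c == 0 for c in cells):
        rna_x, rna_y, dna_x, dna_y = (c + 0.5 for c in cells)
    return (rna_x / rna_y) / (dna_x / dna_y)


def apply_read_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with fewer than MIN_READS RNA reads in both alleles."""
    keep = (records["rna_x"] >= MIN_READS) | (records["rna_y"] >= MIN_READS)
    return records[keep].reset_index(drop=True)


def test_allele_bias(records: pd.DataFrame, alpha_fdr: float = 0.05
                     ) -> tuple[pd.DataFrame, dict]:
    """Per-gene Fisher tests + BH FDR + bias calls, and a binomial summary.

    ``records`` needs columns gene, rna_x, rna_y, dna_x, dna_y.  Returns
    the filtered table with corrected_fold, p_raw, p_fdr and bias_call
    columns, plus a summary dict with the exact two-sided binomial p for
    #neoX-biased vs #neoY-biased against 0.5.
    """
    if records.empty:
        raise ValueError("empty record set")
    df = apply_read_filter(records).copy()
    folds, praw = [], []
    for row in df.itertuples(index=False):
        folds.append(corrected_fold_difference(row.rna_x, row.rna_y, row.dna_x, row.dna_y))
        table = [[row.rna_x, row.rna_y], [row.dna_x, row.dna_y]]
        praw.append(stats.fisher_exact(table, alternative="two-sided")[1])
    df["corrected_fold"] = folds
    df["p_raw"] = praw
    if len(df):
        df["p_fdr"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    else:
        df["p_fdr"] = []
    sig = df["p_fdr"] < alpha_fdr
    df["bias_call"] = "none"
    df.loc[sig & (df["corrected_fold"] > 1), "bias_call"] = "neoX"
    df.loc[sig & (df["corrected_fold"] < 1), "bias_call"] = "neoY"
    n_x = int((df["bias_call"] == "neoX").sum())
    n_y = int((df["bias_call"] == "neoY").sum())
    summary = {
        "n_genes": len(df),
        "n_neoX_biased": n_x,
        "n_neoY_biased": n_y,
        "binomial_p": binomial_bias_p(n_x, n_y),
    }
    return df, summary


def binomial_bias_p(n_neoX: int, n_neoY: int) -> float:
    """Exact two-sided binomial p for the neo-X/neo-Y biased gene split."""
    n = n_neoX + n_neoY
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_neoX, n, 0.5, alternative="two-sided").pvalue)


def validate_fold_recovery(ratios: list[float], depth: float = 300.0,
                           n_genes: int = 1000, seed: int = 0) -> dict[float, float]:
    """Median corrected fold recovered from simulated counts per true ratio."""
    if n_genes < 50:
        log.warning("n_genes < 50: median fold estimate will be unstable")
    out: dict[float, float] = {}
    for i, r in enumerate(ratios):
        if r <= 0:
            raise ValueError("ratios must be positive")
        cfg = SimulationConfig(n_genes=n_genes, ase_ratios=r, dna_depth=depth,
                               rna_depth=depth, seed=seed + i)
        dna, rna = simulate_allele_counts(cfg)
        folds = [
            corrected_fold_difference(rx, ry, dx, dy)
            for rx, ry, dx, dy in zip(rna["count_x"], rna["count_y"],
                                      dna["count_x"], dna["count_y"])
            if max(rx, ry) >= MIN_READS and not (rx == 0 or ry == 0 or dx == 0 or dy == 0)
        ]
        out[r] = float(np.median(folds))
    return out


# ---------------------------------------------------------------------------
# allele-specific ChIP window enrichment
# ---------------------------------------------------------------------------

def chip_window_enrichment(ip_counts: pd.DataFrame, input_counts: pd.DataFrame,
                           autosomal_median: dict[tuple[str, int], float] | float,
                           window: int = 50_000,
                           chrom_length: int | None = None) -> pd.DataFrame:
    """Windowed allele-specific ChIP enrichment.

    ``ip_counts`` / ``input_counts`` need columns pos (1-based), allele
    ({neoX, neoY}), rep, count.  Site counts are normalized by the median
    autosomal coverage of their library (keyed by ('ip'|'input', rep), or a
    single scalar); site enrichment is norm_ip / norm_input, windows
    average sites, and the SE is taken over replicate libraries.  Sites
    with zero input are skipped and counted.
    """

    def norm(kind: str, rep: int) -> float:
        if isinstance(autosomal_median, dict):
            v = autosomal_median[(kind, rep)]
        else:
            v = autosomal_median
        if v <= 0:
            raise ValueError("autosomal coverage must be positive")
        return v

    merged = ip_counts.merge(input_counts, on=["pos", "allele", "rep"],
                             suffixes=("_ip", "_in"))
    n_skipped = int((merged["count_in"] == 0).sum())
    if n_skipped:
        log.warning("%d sites with zero input coverage skipped", n_skipped)
    merged = merged[merged["count_in"] > 0].copy()
    merged["enrichment"] = [
        (row.count_ip / norm("ip", row.rep)) / (row.count_in / norm("input", row.rep))
        for row in merged.itertuples(index=False)
    ]
    merged["win"] = (merged["pos"] - 1) // window
    end = chrom_length or int(merged["pos"].max() if len(merged) else 0)
    rows = []
    for (w, allele), sub in merged.groupby(["win", "allele"]):
        per_rep = sub.groupby("rep")["enrichment"].mean()
        value = float(per_rep.mean())
        se = float(per_rep.std(ddof=1) / np.sqrt(len(per_rep))) if len(per_rep) > 1 else 0.0
        rows.append(("neo", int(w) * window, min((int(w) + 1) * window, end), allele,
                     value, se, len(sub)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "allele", "enrichment",
                                       "se", "n_sites"])
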