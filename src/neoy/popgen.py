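"""Windowed nucleotide diversity, differentiation and divergence.

Haplotypes are haploid variant dictionaries ({1-based pos -> allele},
``None`` marking an explicitly missing call); positions not listed carry
the reference allele.  Window values use the full window length in bp as
the denominator (the vcftools ``--window-pi`` convention): monomorphic
and uncalled bases contribute zero.  Missing calls are dropped per site
(pairwise-complete).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

Haplotypes = dict[str, dict[int, str | None]]


def _ref_base(ref, pos: int) -> str:
    # pos is 1-based
    if isinstance(ref, dict):
        return ref[pos]
    b = ref[pos - 1]
    return chr(b) if isinstance(b, (int, np.integer)) else b


def _site_alleles(haps: Haplotypes, labels: list[str], ref, pos: int) -> list[str]:
    out = []
    for lab in labels:
        muts = haps[lab]
        a = muts.get(pos, _ref_base(ref, pos))
        if a is not None:
            out.append(a)
    return out


def _union_positions(haps: Haplotypes, labels: list[str]) -> list[int]:
    pos: set[int] = set()
    for lab in labels:
        pos.update(haps[lab])
    return sorted(pos)


def _pi_site(alleles: list[str]) -> float | None:
    k = len(alleles)
    if k < 2:
        return None
    c = Counter(alleles)
    return sum(n * (k - n) for n in c.values()) / (k * (k - 1))


def _dxy_site(a: list[str], b: list[str]) -> float | None:
    if not a or not b:
        return None
    ca, cb = Counter(a), Counter(b)
    n1, n2 = len(a), len(b)
    diff = sum(ca[al] * (n2 - cb.get(al, 0)) for al in ca)
    return diff / (n1 * n2)


def _windows(chrom_length: int, window: int) -> list[tuple[int, int]]:
    return [(s, min(s + window, chrom_length))
            for s in range(0, chrom_length, window)]


def windowed_pi(haps: Haplotypes, labels: list[str], ref, chrom_length: int,
                window: int = 50_000, chrom: str = "neo") -> pd.DataFrame:
    """Per-window nucleotide diversity (per bp) over a set of haplotypes."""
    if len(labels) < 2:
        raise ValueError("need at least 2 haplotypes")
    if window <= 0:
        raise ValueError("window must be positive")
    positions = _union_positions(haps, labels)
    persite = {}
    for p in positions:
        v = _pi_site(_site_alleles(haps, labels, ref, p))
        if v is not None:
            persite[p] = v
    rows = []
    for start, end in _windows(chrom_length, window):
        in_win = [p for p in persite if start < p <= end]
        value = sum(persite[p] for p in in_win) / (end - start)
        rows.append((chrom, start, end, "pi", "+".join(labels[:1]) + "...", "", value,
                     len(in_win)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat", "pop1", "pop2",
                                       "value", "n_sites"])


def _wc_components(a1: list[str], a2: list[str]) -> tuple[float, float] | None:
    """Haploid Weir-Cockerham variance components (a, b) for one biallelic site.

    One-way ANOVA on allele indicators: a estimates the between-population
    component, b the within-population component; theta-hat = a / (a + b).
    """
    n1, n2 = len(a1), len(a2)
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        return None
    alleles = sorted(set(a1) | set(a2))
    if len(alleles) != 2:
        return None
    alt = alleles[1]
    p1 = a1.count(alt) / n1
    p2 = a2.count(alt) / n2
    n_tot = n1 + n2
    n_c = n_tot - (n1 * n1 + n2 * n2) / n_tot
    if n_c <= 0:
        return None
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    msb = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2  # df = r - 1 = 1
    df_w = (n1 - 1) + (n2 - 1)
    if df_w <= 0:
        return None
    msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / df_w
    a = (msb - msw) / n_c
    b = msw
    return a, b


def windowed_fst(haps: Haplotypes, pop_a: list[str], pop_b: list[str], ref,
                 chrom_length: int, window: int = 50_000,
                 estimator: str = "weir_cockerham", chrom: str = "neo") -> pd.DataFrame:
    """Windowed F_ST between two haplotype sets (ratio-of-sums across sites)."""
    if not pop_a or not pop_b:
        raise ValueError("empty population")
    if estimator not in ("weir_cockerham", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    positions = _union_positions(haps, pop_a + pop_b)
    per_win: dict[int, list[tuple[float, float]]] = {}
    for p in positions:
        sa = _site_alleles(haps, pop_a, ref, p)
        sb = _site_alleles(haps, pop_b, ref, p)
        if estimator == "weir_cockerham":
            comp = _wc_components(sa, sb)
            if comp is None:
                continue
            num, den = comp[0], comp[0] + comp[1]
        else:
            hw_a, hw_b = _pi_site(sa), _pi_site(sb)
            hb = _dxy_site(sa, sb)
            if hw_a is None or hw_b is None or hb is None:
                continue
            num, den = hb - (hw_a + hw_b) / 2.0, hb
        per_win.setdefault((p - 1) // window, []).append((num, den))
    rows = []
    for start, end in _windows(chrom_length, window):
        comps = per_win.get(start // window, [])
        num = sum(c[0] for c in comps)
        den = sum(c[1] for c in comps)
        value = num / den if den > 0 else float("nan")
        rows.append((chrom, start, end, f"fst_{estimator}", "A", "B", value, len(comps)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat", "pop1", "pop2",
                                       "value", "n_sites"])


def windowed_divergence(haps: Haplotypes, pop_a: list[str], pop_b: list[str], ref,
                        chrom_length: int, window: int = 50_000,
                        chrom: str = "neo") -> pd.DataFrame:
    """Windowed absolute (D_XY) and net (D_A = D_XY - (pi_A + pi_B)/2) divergence.

    Negative D_A values are reported, not clipped.
    """
    if not pop_a or not pop_b:
        raise ValueError("empty population")
    positions = _union_positions(haps, pop_a + pop_b)
    dxy_site: dict[int, float] = {}
    pia_site: dict[int, float] = {}
    pib_site: dict[int, float] = {}
    for p in positions:
        sa = _site_alleles(haps, pop_a, ref, p)
        sb = _site_alleles(haps, pop_b, ref, p)
        d = _dxy_site(sa, sb)
        if d is not None:
            dxy_site[p] = d
        va, vb = _pi_site(sa), _pi_site(sb)
        if va is not None:
            pia_site[p] = va
        if vb is not None:
            pib_site[p] = vb
    rows = []
    for start, end in _windows(chrom_length, window):
        L = end - start
        sel = lambda d: sum(v for p, v in d.items() if start < p <= end)  # noqa: E731
        dxy = sel(dxy_site) / L
        pia = sel(pia_site) / L
        pib = sel(pib_site) / L
        da = dxy - (pia + pib) / 2.0
        n = sum(1 for p in dxy_site if start < p <= end)
        rows.append((chrom, start, end, "dxy", "A", "B", dxy, n))
        rows.append((chrom, start, end, "da", "A", "B", da, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat", "pop1", "pop2",
                                       "value", "n_sites"])
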