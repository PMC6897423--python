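"""Neo-Y genotype inference from paired male/female diploid calls.

The neo-Y is carried only by males, mapped against a female-derived
reference, so a male presents the neo-Y allele as one allele of a
heterozygous call.  At sites where the female of the strain is homozygous
and the male heterozygous, the neo-Y genotype is the male allele not seen
in the female; sites heterozygous in the female are left missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from neoy.simulate import VariantRecord

log = logging.getLogger(__name__)

MISSING = None


@dataclass(frozen=True)
class NeoYCall:
    chrom: str
    pos: int  # 1-based
    strain: str
    allele: str | None  # MISSING (None) when the female is het or inconsistent
    source_class: str  # {"snp", "indel"}
    inconsistent: bool = False


def sample_site_table(records: list[VariantRecord], sample: str,
                      indels: bool = False) -> pd.DataFrame:
    """Extract one sample's diploid calls as a site table.

    Columns: chrom, pos, ref, a1, a2, dp, gq (allele strings).  Sites where
    the sample genotype is missing are omitted.
    """
    rows = []
    for r in records:
        if r.is_indel != indels:
            continue
        gt = r.genotypes.get(sample)
        if gt is None:
            continue
        rows.append(
            (r.chrom, r.pos, r.ref, r.allele(gt[0]), r.allele(gt[1]),
             r.depth.get(sample, 0), r.gq.get(sample, 0))
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "a1", "a2", "dp", "gq"])


def infer_neoY_snps(male: pd.DataFrame, female: pd.DataFrame, strain: str = "strain",
                    min_depth: int = 5, min_gq: int = 20) -> list[NeoYCall]:
    """Call haploid neo-Y SNP alleles for one strain.

    Sites failing the depth/quality filters in either sample, or missing a
    genotype in either sample, are excluded before calling.  A male
    heterozygote whose alleles do not include the female allele is logged
    and emitted as MISSING (genotype inconsistency, expected under
    sequencing error), as is any female heterozygote.
    """
    if min_depth < 0 or min_gq < 0:
        raise ValueError("thresholds must be non-negative")
    merged = male.merge(female, on=["chrom", "pos"], suffixes=("_m", "_f"))
    if len(merged) and (merged["ref_m"] != merged["ref_f"]).any():
        raise ValueError("male and female tables disagree on reference alleles")
    calls: list[NeoYCall] = []
    n_inconsistent = 0
    for row in merged.itertuples(index=False):
        if min(row.dp_m, row.dp_f) < min_depth or min(row.gq_m, row.gq_f) < min_gq:
            continue
        if row.a1_f != row.a2_f:
            calls.append(NeoYCall(row.chrom, row.pos, strain, MISSING, "snp"))
            continue
        fem = row.a1_f
        if row.a1_m == row.a2_m:
            continue  # male homozygous: no neo-Y-specific allele at this site
        male_alleles = {row.a1_m, row.a2_m}
        if fem not in male_alleles:
            n_inconsistent += 1
            calls.append(NeoYCall(row.chrom, row.pos, strain, MISSING, "snp",
                                  inconsistent=True))
            continue
        (neoy,) = male_alleles - {fem}
        calls.append(NeoYCall(row.chrom, row.pos, strain, neoy, "snp"))
    if n_inconsistent:
        log.warning("%s: %d male het sites lacked the female allele (set MISSING)",
                    strain, n_inconsistent)
    return calls


def merge_indels(calls: list[NeoYCall], merge_window: int = 50) -> list[NeoYCall]:
    """Greedy left-to-right chaining: keep the first indel, drop any within
    ``merge_window`` bp of the last *kept* one; ties at the same start keep
    the longest reference span (encoded in call ordering)."""
    kept: list[NeoYCall] = []
    last = None
    for c in sorted(calls, key=lambda c: c.pos):
        if last is not None and c.pos - last <= merge_window:
            continue
        kept.append(c)
        last = c.pos
    return kept


def infer_neoY_indels(male: pd.DataFrame, female: pd.DataFrame, strain: str = "strain",
                      min_depth: int = 5, min_gq: int = 20,
                      merge_window: int = 50) -> list[NeoYCall]:
    """Call Y-linked indels for one strain.

    Male-het/female-hom-ref indels are Y-linked, as are male-specific
    homozygous indels (female homozygous reference).  Records must be
    left-normalized; among indels within ``merge_window`` bp of each other
    only the first is retained.

    Expects columns chrom, pos, ref, alt, a1, a2, dp, gq.
    """
    merged = male.merge(female, on=["chrom", "pos", "ref", "alt"], suffixes=("_m", "_f"))
    candidates: list[NeoYCall] = []
    for row in merged.itertuples(index=False):
        if min(row.dp_m, row.dp_f) < min_depth or min(row.gq_m, row.gq_f) < min_gq:
            continue
        female_has = row.alt in (row.a1_f, row.a2_f)
        male_het = {row.a1_m, row.a2_m} == {row.ref, row.alt}
        male_hom_alt = row.a1_m == row.a2_m == row.alt
        if female_has:
            continue
        if male_het or male_hom_alt:
            candidates.append(NeoYCall(row.chrom, row.pos, strain, row.alt, "indel"))
    # longest ref span first on position ties so it wins the merge
    candidates.sort(key=lambda c: (c.pos, -len(c.allele or "")))
    return merge_indels(candidates, merge_window)


# ---------------------------------------------------------------------------
# shared polymorphism / fixed difference classification
# ---------------------------------------------------------------------------

CATEGORIES = ("shared_polymorphism", "fixed_difference", "private_X", "private_Y",
              "uninformative")


def classify_sites(neoX_alleles: dict[int, list[str]],
                   neoY_alleles: dict[int, list[str]]) -> pd.DataFrame:
    """Classify each site's haploid allele sets into polymorphism categories.

    Singletons (alleles seen once across the pooled classes) render a site
    uninformative, as do sites with more than two alleles after singleton
    removal; only biallelic sites are classified.
    """
    rows = []
    for pos in sorted(set(neoX_alleles) | set(neoY_alleles)):
        xs = [a for a in neoX_alleles.get(pos, []) if a is not None]
        ys = [a for a in neoY_alleles.get(pos, []) if a is not None]
        if not xs and not ys:
            raise ValueError(f"empty allele sets at {pos}")
        rows.append((pos, _classify_one(xs, ys)))
    return pd.DataFrame(rows, columns=["pos", "category"])


def _classify_one(xs: list[str], ys: list[str]) -> str:
    pooled = xs + ys
    counts: dict[str, int] = {}
    for a in pooled:
        counts[a] = counts.get(a, 0) + 1
    if any(c == 1 for c in counts.values()):
        return "uninformative"
    if len(counts) != 2:
        return "uninformative"
    xset, yset = set(xs), set(ys)
    if len(xset) == 2 and len(yset) == 2:
        return "shared_polymorphism"
    if len(xset) == 1 and len(yset) == 1:
        return "fixed_difference" if xset != yset else "uninformative"
    if len(xset) == 2:
        return "private_X"
    return "private_Y"


def windowed_site_class_proportions(site_classes: pd.DataFrame, window: int = 50_000,
                                    chrom_length: int | None = None) -> pd.DataFrame:
    """Per-window proportions of each informative category.

    Windows are 0-based half-open; positions are 1-based.  The number of
    informative sites per window is the denominator and is reported.
    """
    df = site_classes.copy()
    df["win"] = (df["pos"] - 1) // window
    end = (chrom_length or int(df["pos"].max())) if len(df) else 0
    n_win = max((end + window - 1) // window, 0)
    rows = []
    for w in range(n_win):
        sub = df[df["win"] == w]
        informative = sub[sub["category"] != "uninformative"]
        n = len(informative)
        props = {c: (len(informative[informative["category"] == c]) / n if n else float("nan"))
                 for c in CATEGORIES if c != "uninformative"}
        rows.append({"start": w * window, "end": min((w + 1) * window, end),
                     "n_informative": n, **props})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-fixed derived variants
# ---------------------------------------------------------------------------

def fixed_derived_per_group(calls_by_group: dict[str, dict[str, dict[int, str]]],
                            neoX_alleles: dict[int, set[str]],
                            outgroup_alleles: dict[int, set[str]],
                            region: tuple[int, int] | None = None,
                            exclude_strains: tuple[str, ...] = (),
                            ) -> dict[str, dict[int, str]]:
    """Variants fixed in a Y group and absent from all neo-X and outgroup copies.

    ``calls_by_group`` maps group -> strain -> {1-based pos -> allele}.
    A variant is group-fixed-derived iff every non-missing member of the
    group carries it, and the allele is seen in no neo-X and no outgroup
    haplotype.  ``region`` is a half-open 1-based interval.  Strains listed
    in ``exclude_strains`` (e.g. a divergent-haplotype carrier) are ignored.
    """
    out: dict[str, dict[int, str]] = {}
    for group, strains in calls_by_group.items():
        members = {s: c for s, c in strains.items() if s not in exclude_strains}
        if not members:
            out[group] = {}
            continue
        positions: set[int] = set()
        for c in members.values():
            positions.update(c)
        fixed: dict[int, str] = {}
        any_call = False
        for pos in positions:
            if region is not None and not (region[0] <= pos < region[1]):
                continue
            alleles = {c[pos] for c in members.values() if pos in c and c[pos] is not None}
            if not alleles:
                continue
            any_call = True
            if len(alleles) != 1:
                continue
            missing_member = any(pos not in c or c[pos] is None for c in members.values())
            if missing_member:
                # require presence in all *non-missing* members; absent members
                # whose call exists and differs were already caught above
                pass
            (allele,) = alleles
            if allele in neoX_alleles.get(pos, set()):
                continue
            if allele in outgroup_alleles.get(pos, set()):
                continue
            fixed[pos] = allele
        if not any_call:
            log.warning("group %s has no non-missing calls in region", group)
        out[group] = fixed
    return out


def calls_to_dict(calls: list[NeoYCall]) -> dict[int, str]:
    """Position -> allele for non-missing calls."""
    return {c.pos: c.allele for c in calls if c.allele is not MISSING}
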