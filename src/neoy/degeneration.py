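"""Coding-effect classification of fixed neo-Y variants and NG86 Ka/Ks.

Substitutions are applied to the reference CDS one at a time for effect
classes (synonymous / nonsynonymous / nonsense on the transcript strand);
indels are frameshifts when their length is not a multiple of 3.  Ka/Ks
uses the Nei-Gojobori (1986) method: expected synonymous/nonsynonymous
site counts averaged over both sequences, pathway-averaged difference
counting for multi-hit codons, and Jukes-Cantor correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import pandas as pd

from neoy._codon import COMPLEMENT, translate_codon
from neoy.annotation import GeneModel

log = logging.getLogger(__name__)

EFFECTS = ("synonymous", "nonsynonymous", "nonsense", "frameshift", "inframe_indel",
           "near_gene_500bp", "intergenic")


@dataclass(frozen=True)
class CdsVariantEffect:
    pos: int  # 1-based
    gene: str | None
    effect: str
    group: str


@dataclass(frozen=True)
class KaKsRecord:
    gene: str
    group: str
    ka: float
    ks: float

    @property
    def ratio(self) -> float | None:
        if self.ks == 0:
            return None
        return self.ka / self.ks


def extract_cds(reference: str, gene: GeneModel) -> str:
    seq = reference[gene.start - 1:gene.end]
    if gene.strand == "-":
        seq = "".join(COMPLEMENT[b] for b in reversed(seq))
    return seq


def classify_snp_effects(variants: dict[str, dict[int, str]], genes: list[GeneModel],
                         reference: str,
                         region: tuple[int, int] | None = None,
                         ) -> tuple[list[CdsVariantEffect], pd.DataFrame]:
    """Classify fixed SNPs per group by codon-level effect.

    ``variants`` maps group -> {1-based pos -> alt allele}.  Variants are
    applied to the reference codon one at a time; effects are computed on
    the transcript strand.  Genes whose CDS length is not a multiple of 3
    are skipped with a log message.  Returns per-variant effects plus a
    per-group count table over effect classes (intergenic/near-gene SNPs
    are reported as 'intergenic').
    """
    ok_genes = []
    for g in genes:
        if g.length % 3 != 0:
            log.warning("gene %s: CDS length not a multiple of 3; skipped", g.name)
            continue
        ok_genes.append(g)
    effects: list[CdsVariantEffect] = []
    for group, muts in variants.items():
        for pos, alt in sorted(muts.items()):
            if region is not None and not (region[0] <= pos < region[1]):
                continue
            gene = next((g for g in ok_genes if g.contains(pos)), None)
            if gene is None:
                effects.append(CdsVariantEffect(pos, None, "intergenic", group))
                continue
            effects.append(CdsVariantEffect(pos, gene.name,
                                            _snp_effect_in_gene(reference, gene, pos, alt),
                                            group))
    counts = _count_table(effects)
    return effects, counts


def _snp_effect_in_gene(reference: str, gene: GeneModel, pos: int, alt: str) -> str:
    off = gene.cds_offset(pos)
    ci, cp = divmod(off, 3)
    cds = extract_cds(reference, gene)
    codon = cds[3 * ci:3 * ci + 3]
    base = alt if gene.strand == "+" else COMPLEMENT[alt]
    mutated = codon[:cp] + base + codon[cp + 1:]
    aa0, aa1 = translate_codon(codon), translate_codon(mutated)
    if aa1 == aa0:
        return "synonymous"
    if aa1 == "*":
        return "nonsense"
    return "nonsynonymous"


def classify_indel_effects(indels: dict[str, list[tuple[int, int]]],
                           genes: list[GeneModel], flank: int = 500,
                           region: tuple[int, int] | None = None,
                           ) -> tuple[list[CdsVariantEffect], pd.DataFrame]:
    """Classify fixed indels: ``indels`` maps group -> [(1-based pos, length change)].

    CDS indels with length % 3 != 0 are frameshifts, otherwise in-frame;
    non-CDS indels within ``flank`` bp of a gene span are near-gene, the
    rest intergenic.
    """
    effects: list[CdsVariantEffect] = []
    for group, recs in indels.items():
        for pos, dlen in sorted(recs):
            if region is not None and not (region[0] <= pos < region[1]):
                continue
            gene = next((g for g in genes if g.contains(pos)), None)
            if gene is not None:
                eff = "frameshift" if dlen % 3 != 0 else "inframe_indel"
                effects.append(CdsVariantEffect(pos, gene.name, eff, group))
                continue
            near = next((g for g in genes
                         if g.start - flank <= pos <= g.end + flank), None)
            if near is not None:
                effects.append(CdsVariantEffect(pos, near.name, "near_gene_500bp", group))
            else:
                effects.append(CdsVariantEffect(pos, None, "intergenic", group))
    return effects, _count_table(effects)


def _count_table(effects: list[CdsVariantEffect]) -> pd.DataFrame:
    rows = []
    for group in sorted({e.group for e in effects}):
        sub = [e for e in effects if e.group == group]
        rows.append({"group": group, "total": len(sub),
                     **{eff: sum(1 for e in sub if e.effect == eff) for eff in EFFECTS}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _codon_sites(codon: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes creating a stop codon count as
    nonsynonymous.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all
    mutational pathways between two codons; pathways passing through a
    stop codon are excluded when any stop-free pathway exists."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            if translate_codon(nxt) == "*":
                through_stop = True
            cur = nxt
        paths.append((sd, nd, through_stop))
    clean = [p for p in paths if not p[2]]
    use = clean or paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jc(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")  # saturated
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def compute_kaks(cds_x: str, cds_y: str, gene: str = "gene",
                 group: str = "group") -> KaKsRecord:
    """NG86 Ka and Ks between two in-frame, equal-length coding sequences."""
    if len(cds_x) != len(cds_y):
        raise ValueError("length mismatch")
    if len(cds_x) % 3 != 0:
        raise ValueError("sequences not in frame")
    if cds_x == cds_y:
        raise ValueError("identical sequences are excluded upstream")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_x), 3):
        c1, c2 = cds_x[i:i + 3], cds_y[i:i + 3]
        if translate_codon(c1) == "*" or translate_codon(c2) == "*":
            if i + 3 < len(cds_x):  # internal stop
                raise ValueError(f"{gene}: internal stop codon")
            continue  # terminal stop codon excluded from site counts
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KaKsRecord(gene, group, ka=_jc(pn), ks=_jc(ps))


def group_cds(reference: str, gene: GeneModel, fixed_snps: dict[int, str]) -> str:
    """CDS with a group's fixed substitutions applied (genomic coordinates)."""
    seq = list(reference)
    for pos, alt in fixed_snps.items():
        if gene.contains(pos):
            seq[pos - 1] = alt
    return extract_cds("".join(seq), gene)


def kaks_per_group(reference: str, genes: list[GeneModel],
                   fixed_by_group: dict[str, dict[int, str]]) -> list[KaKsRecord]:
    """Per-gene NG86 records per group; genes identical to the neo-X copy
    are removed, genes with internal stops are flagged and skipped."""
    out: list[KaKsRecord] = []
    for group, fixed in fixed_by_group.items():
        for gene in genes:
            if gene.length % 3 != 0:
                continue
            x_cds = extract_cds(reference, gene)
            y_cds = group_cds(reference, gene, fixed)
            if x_cds == y_cds:
                continue
            try:
                out.append(compute_kaks(x_cds, y_cds, gene.name, group))
            except ValueError as exc:
                log.warning("%s/%s skipped: %s", group, gene.name, exc)
    return out
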