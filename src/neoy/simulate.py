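"""Synthetic cohort generator.

Produces diploid genotype tables, a reference sequence, gene annotation,
allele-specific count tables, tissue expression matrices, and a truth set
with the statistical structure the downstream analyses assume:

* two sister lineages split ``species_split_kya`` ago (ingroup vs outgroup);
* neo-X haplotypes carrying standing diversity (star genealogy at rate
  ``theta/2`` per haplotype, mutations stamped with a uniform age);
* neo-Y founders that are recombinant mosaics of neo-X donor haplotypes
  switching at configured breakpoints, plus an outgroup-derived block;
* per-group recombination-stop times after which each Y group evolves
  clonally, fixing ``Poisson(mu * L * stop_kya)`` substitutions and
  ``Poisson(indel_rate * L * stop_kya)`` indels.

Females are emitted as neoX/neoX diploids, males as neoX/neoY
heterozygotes (the neo-Y allele is the second allele of the het call),
and outgroup strains as homozygous outgroup diploids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from neoy._codon import COMPLEMENT, translate_codon
from neoy.annotation import GeneModel
from neoy.config import SimulationConfig

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
CHROM = "neo"

OUTGROUP_LABEL = "nasuta"
PROTO_LABEL = "protoY"
# when (as fractions of the species-split age) the sampled outgroup strains
# diverged from each other, and the outgroup-derived neo-Y block diverged
# from the first outgroup strain's lineage
OUTGROUP_CROWN_FRACTION = 0.6
BLOCK_AGE_FRACTION = 0.3


@dataclass(frozen=True)
class IndelRecord:
    """A left-anchored VCF-style indel carried by one neo-Y group."""

    pos: int  # 1-based position of the anchor base
    ref: str
    alt: str
    group: str

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class TruthSet:
    """Ground truth for every simulated event.

    ``segments`` maps each neo-Y strain to ``(start, end, donor)`` tuples in
    0-based half-open coordinates tiling the chromosome; ``neoY_snps`` maps
    each strain to its full haploid variant state keyed by 1-based position.
    """

    segments: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    breakpoints: dict[str, list[int]] = field(default_factory=dict)
    stop_kya: dict[str, float] = field(default_factory=dict)
    neoY_snps: dict[str, dict[int, str]] = field(default_factory=dict)
    group_private_snps: dict[str, list[int]] = field(default_factory=dict)
    group_indels: dict[str, list[IndelRecord]] = field(default_factory=dict)
    snp_effects: dict[int, tuple[str, str]] = field(default_factory=dict)  # pos -> (group, effect)
    indel_effects: dict[int, tuple[str, str]] = field(default_factory=dict)
    ase_ratios: dict[str, float] = field(default_factory=dict)
    tissue_bias: dict[str, str | None] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {
            "segments": self.segments,
            "breakpoints": self.breakpoints,
            "stop_kya": self.stop_kya,
            "neoY_snps": {s: {str(p): a for p, a in v.items()} for s, v in self.neoY_snps.items()},
            "group_private_snps": self.group_private_snps,
            "group_indels": {
                g: [[r.pos, r.ref, r.alt] for r in v] for g, v in self.group_indels.items()
            },
            "snp_effects": {str(p): list(v) for p, v in self.snp_effects.items()},
            "indel_effects": {str(p): list(v) for p, v in self.indel_effects.items()},
            "ase_ratios": self.ase_ratios,
            "tissue_bias": self.tissue_bias,
        }
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass
class Cohort:
    """In-memory simulated cohort; haplotypes are haploid SNP states."""

    config: SimulationConfig
    reference: np.ndarray  # uint8 array of A/C/G/T codes
    genes: list[GeneModel]
    truth: TruthSet
    # haploid SNP states, 0-based pos -> alt base (positions absent are reference)
    neoX_haplotypes: dict[str, dict[int, str]]
    neoY_haplotypes: dict[str, dict[int, str]]
    outgroup_haplotypes: dict[str, dict[int, str]]
    # strain -> neo-X haplotype label carried by that strain
    strain_x: dict[str, str]
    group_indels: dict[str, list[IndelRecord]]

    @property
    def reference_str(self) -> str:
        return self.reference.tobytes().decode()

    def all_haplotypes(self) -> dict[str, dict[int, str]]:
        out = dict(self.neoX_haplotypes)
        for strain, muts in self.neoY_haplotypes.items():
            out[f"{strain}.Y"] = muts
        out.update(self.outgroup_haplotypes)
        return out

    def haplotype_sequence(self, label: str) -> np.ndarray:
        """Materialize a haploid sequence (uint8) by applying SNPs to the reference."""
        seq = self.reference.copy()
        muts = self.all_haplotypes()[label]
        if muts:
            pos = np.fromiter(muts.keys(), dtype=np.int64)
            alt = np.frombuffer("".join(muts.values()).encode(), dtype=np.uint8)
            seq[pos] = alt
        return seq

    def haplotype_class(self) -> dict[str, str]:
        """Label -> {neoX, <group name>, outgroup} for tree classification."""
        classes = {lab: "neoX" for lab in self.neoX_haplotypes}
        g_of = self.config.group_of_strain()
        for strain in self.neoY_haplotypes:
            classes[f"{strain}.Y"] = g_of[strain]
        for lab in self.outgroup_haplotypes:
            classes[lab] = "outgroup"
        return classes


def _mutate(rng: np.random.Generator, L: int, n: int, ref: np.ndarray,
            forbidden: set[int] | None = None) -> dict[int, str]:
    """Place n substitutions at distinct positions, optionally avoiding a set."""
    muts: dict[int, str] = {}
    while len(muts) < n:
        pos = int(rng.integers(0, L))
        if pos in muts or (forbidden is not None and pos in forbidden):
            continue
        alt = chr(BASES[(np.searchsorted(BASES, ref[pos]) + int(rng.integers(1, 4))) % 4])
        muts[pos] = alt
    return muts


def _mutate_region(rng: np.random.Generator, start: int, end: int, n: int,
                   ref: np.ndarray, forbidden: set[int] | None = None) -> dict[int, str]:
    """Place n substitutions at distinct positions within [start, end)."""
    muts: dict[int, str] = {}
    if end <= start:
        return muts
    while len(muts) < n:
        pos = int(rng.integers(start, end))
        if pos in muts or (forbidden is not None and pos in forbidden):
            continue
        alt = chr(BASES[(np.searchsorted(BASES, ref[pos]) + int(rng.integers(1, 4))) % 4])
        muts[pos] = alt
    return muts


def _snp_effect(genes: list[GeneModel], ref: np.ndarray, pos0: int, alt: str) -> str:
    """Coding effect of a single substitution against the plain reference."""
    for g in genes:
        if g.contains(pos0 + 1):
            off = g.cds_offset(pos0 + 1)
            ci = off // 3
            if g.strand == "+":
                start0 = g.start - 1 + 3 * ci
                codon = ref[start0:start0 + 3].tobytes().decode()
                mut = list(codon)
                mut[off % 3] = alt
            else:
                end0 = g.end - 1 - 3 * ci
                codon = "".join(COMPLEMENT[chr(b)] for b in ref[end0 - 2:end0 + 1][::-1])
                mut = list(codon)
                mut[off % 3] = COMPLEMENT[alt]
            aa0, aa1 = translate_codon(codon), translate_codon("".join(mut))
            if aa1 == aa0:
                return "synonymous"
            if aa1 == "*":
                return "nonsense"
            return "nonsynonymous"
    return "noncoding"


def _indel_effect(genes: list[GeneModel], pos: int, length_change: int, flank: int = 500) -> str:
    for g in genes:
        if g.contains(pos):
            return "frameshift" if length_change % 3 != 0 else "inframe_indel"
    for g in genes:
        if g.start - flank <= pos <= g.end + flank:
            return "near_gene_500bp"
    return "intergenic"


def _default_genes(cfg: SimulationConfig) -> list[GeneModel]:
    genes: list[GeneModel] = []
    if cfg.n_genes == 0:
        return genes
    pitch = cfg.chromosome_length // cfg.n_genes
    if pitch <= cfg.gene_length:
        raise ValueError("genes do not fit on the chromosome")
    for i in range(cfg.n_genes):
        start = i * pitch + (pitch - cfg.gene_length) // 2  # 0-based
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(f"gene{i:04d}", CHROM, start + 1, start + cfg.gene_length, strand)
        )
    return genes


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Simulate the full cohort: haplotypes, genes, indels, and truth set."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.chromosome_length
    T_s = config.species_split_kya
    ref = BASES[rng.integers(0, 4, size=L)]
    genes = _default_genes(config)

    used: set[int] = set()

    # neo-X haplotypes: star genealogy, per-haplotype rate theta/2, mutations
    # stamped with an age uniform on (0, T_s] so a neo-Y founder copied at
    # stop time t inherits exactly the donor mutations older than t.  One
    # extra hidden lineage ("protoY") is the ancestral Y carried by every
    # group in segments where its founder never recombined; its mutations
    # older than two groups' stop times are shared, making those groups a
    # single exclusively-neo-Y clade there.
    neoX: dict[str, dict[int, str]] = {}
    x_times: dict[str, dict[int, float]] = {}
    for j in range(config.n_neoX + 1):
        lab = f"X{j}" if j < config.n_neoX else PROTO_LABEL
        n = int(rng.poisson(config.theta / 2.0 * L))
        muts = _mutate(rng, L, n, ref)
        neoX[lab] = muts
        x_times[lab] = {p: float(rng.uniform(0.0, T_s)) for p in muts}
        used.update(muts)
    proto = neoX.pop(PROTO_LABEL)
    proto_times = x_times[PROTO_LABEL]

    # outgroup species: a stem from the species split down to the outgroup
    # crown (shared by all outgroup strains and by the introgressed neo-Y
    # block), then a star of per-strain lineages.  The block branches off
    # the first outgroup strain's lineage at BLOCK_AGE_FRACTION x T_s, so
    # neo-Ys carrying it nest *within* the outgroup clade, sister to that
    # strain.
    T_crown = OUTGROUP_CROWN_FRACTION * T_s
    T_block = BLOCK_AGE_FRACTION * T_s
    out_stem = _mutate(rng, L, int(rng.poisson(config.mu * (T_s - T_crown) * L)), ref, used)
    used.update(out_stem)
    outgroup: dict[str, dict[int, str]] = {}
    out_priv_times: dict[str, dict[int, float]] = {}
    for k in range(config.n_outgroup):
        priv = _mutate(rng, L, int(rng.poisson(config.mu * T_crown * L)), ref, used)
        used.update(priv)
        lab = f"{OUTGROUP_LABEL}{k}"
        outgroup[lab] = {**out_stem, **priv}
        out_priv_times[lab] = {p: float(rng.uniform(0.0, T_crown)) for p in priv}
    bs, be = config.nasuta_block
    block_donor = f"{OUTGROUP_LABEL}0"
    block_own = _mutate_region(rng, bs, be,
                               int(rng.poisson(config.mu * T_block * (be - bs))),
                               ref, used)
    used.update(block_own)
    block_state: dict[int, str] = dict(block_own)
    for p, a in out_stem.items():
        if bs <= p < be:
            block_state[p] = a
    for p, a in outgroup[block_donor].items():
        if bs <= p < be and out_priv_times[block_donor].get(p, 0.0) > T_block:
            block_state[p] = a

    truth = TruthSet()
    strain_x: dict[str, str] = {}
    neoY: dict[str, dict[int, str]] = {}
    group_indels: dict[str, list[IndelRecord]] = {}

    strains = config.strain_names()
    for idx, strain in enumerate(strains):
        strain_x[strain] = f"X{idx}"

    strain_cursor = 0
    for g in config.y_groups:
        # donor mosaic of the group founder: each segment either retains the
        # shared proto-Y lineage or was replaced by a sampled neo-X donor
        edges = [0] + list(g.breakpoints) + [L]
        donors: list[str] = []
        for _ in range(len(edges) - 1):
            for _attempt in range(100):
                if rng.random() < config.proto_donor_prob:
                    choice = PROTO_LABEL
                else:
                    choice = f"X{int(rng.integers(0, config.n_neoX))}"
                if not donors or choice != donors[-1]:
                    break
            donors.append(choice)
        founder: dict[int, str] = {}
        segments: list[tuple[int, int, str]] = []
        for (s0, e0), donor in zip(zip(edges[:-1], edges[1:]), donors):
            dm = proto if donor == PROTO_LABEL else neoX[donor]
            dt = proto_times if donor == PROTO_LABEL else x_times[donor]
            for p, a in dm.items():
                if s0 <= p < e0 and dt[p] > g.recomb_stop_kya:
                    founder[p] = a
            segments.append((s0, e0, donor))
        # outgroup-derived block overrides the donor mosaic
        for p in list(founder):
            if bs <= p < be:
                del founder[p]
        founder.update(block_state)
        segments = _overlay_block(segments, bs, be)

        # clonal group-fixed substitutions after the recombination stop
        n_sub = int(rng.poisson(config.mu * L * g.recomb_stop_kya))
        fixed = _mutate(rng, L, n_sub, ref, used)
        used.update(fixed)
        founder.update(fixed)
        truth.group_private_snps[g.name] = sorted(p + 1 for p in fixed)
        for p, a in fixed.items():
            truth.snp_effects[p + 1] = (g.name, _snp_effect(genes, ref, p, a))

        # clonal group-fixed indels
        n_ind = int(rng.poisson(config.indel_rate * L * g.recomb_stop_kya))
        indels: list[IndelRecord] = []
        for _ in range(n_ind):
            while True:
                p = int(rng.integers(0, L - 10))
                if p not in used and p + 1 not in used:
                    break
            used.update(range(p, p + 8))
            size = int(rng.integers(1, 7))
            if rng.random() < 0.5 and p + size + 1 < L:  # deletion
                refseq = ref[p:p + size + 1].tobytes().decode()
                altseq = refseq[0]
            else:  # insertion
                refseq = chr(ref[p])
                ins = "".join(chr(BASES[i]) for i in rng.integers(0, 4, size=size))
                altseq = refseq + ins
            indels.append(IndelRecord(p + 1, refseq, altseq, g.name))
        indels.sort(key=lambda r: r.pos)
        group_indels[g.name] = indels
        truth.group_indels[g.name] = indels
        for r in indels:
            truth.indel_effects[r.pos] = (g.name, _indel_effect(genes, r.pos, r.length_change))

        bps = set(g.breakpoints) | {bs, be}
        truth.breakpoints[g.name] = sorted(b for b in bps if 0 < b < L)
        truth.stop_kya[g.name] = g.recomb_stop_kya

        for _ in range(g.n_strains):
            strain = strains[strain_cursor]
            strain_cursor += 1
            neoY[strain] = dict(founder)
            truth.segments[strain] = segments
            truth.neoY_snps[strain] = {p + 1: a for p, a in founder.items()}

    return Cohort(
        config=config,
        reference=ref,
        genes=genes,
        truth=truth,
        neoX_haplotypes=neoX,
        neoY_haplotypes=neoY,
        outgroup_haplotypes=outgroup,
        strain_x=strain_x,
        group_indels=group_indels,
    )


def _overlay_block(segments: list[tuple[int, int, str]], bs: int, be: int
                   ) -> list[tuple[int, int, str]]:
    """Replace [bs, be) of a tiling segment list with an outgroup-donor segment."""
    out: list[tuple[int, int, str]] = []
    for s0, e0, d in segments:
        if e0 <= bs or s0 >= be:
            out.append((s0, e0, d))
            continue
        if s0 < bs:
            out.append((s0, bs, d))
        if e0 > be:
            out.append((be, e0, d))
    out.append((bs, be, OUTGROUP_LABEL))
    out.sort()
    return out


def donor_at(cohort: Cohort, strain: str, pos0: int) -> str:
    """Truth donor label of a strain's neo-Y at a 0-based position."""
    for s0, e0, d in cohort.truth.segments[strain]:
        if s0 <= pos0 < e0:
            return d
    raise ValueError(f"position {pos0} not covered for {strain}")


def truth_cluster_key(cohort: Cohort, strain: str, pos0: int) -> tuple:
    """Key identifying which strains share a paintable haplotype at a position.

    Two strains fall in the same exclusively-neo-Y clade iff they are in the
    same clonal group, or both retain a shared lineage (proto-Y or the
    outgroup-derived block) at that position.
    """
    donor = donor_at(cohort, strain, pos0)
    if donor in (PROTO_LABEL, OUTGROUP_LABEL):
        return (donor,)
    return (cohort.config.group_of_strain()[strain], donor)


# ---------------------------------------------------------------------------
# diploid genotype table (VCF-shaped records)
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    genotypes: dict[str, tuple[int, int]]
    depth: dict[str, int]
    gq: dict[str, int]
    is_indel: bool = False

    def allele(self, idx: int) -> str:
        return ([self.ref] + self.alts)[idx]


def diploid_samples(cohort: Cohort) -> dict[str, tuple[str, str]]:
    """Sample name -> pair of haploid labels (allele1, allele2)."""
    cfg = cohort.config
    samples: dict[str, tuple[str, str]] = {}
    for strain, xlab in cohort.strain_x.items():
        samples[f"{strain}_F"] = (xlab, xlab)
        samples[f"{strain}_M"] = (xlab, f"{strain}.Y")
    n_strains = len(cohort.strain_x)
    for j in range(n_strains, cfg.n_neoX):
        samples[f"neoX_f{j}"] = (f"X{j}", f"X{j}")
    for lab in cohort.outgroup_haplotypes:
        samples[lab] = (lab, lab)
    return samples


def genotype_records(cohort: Cohort, mean_depth: int = 30,
                     rng: np.random.Generator | None = None) -> list[VariantRecord]:
    """Emit diploid VCF-shaped SNP + indel records for all samples."""
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 1)
    haps = cohort.all_haplotypes()
    samples = diploid_samples(cohort)
    positions: set[int] = set()
    for muts in haps.values():
        positions.update(muts)
    records: list[VariantRecord] = []
    ref = cohort.reference
    for p in sorted(positions):
        refb = chr(ref[p])
        per_sample: dict[str, tuple[str, str]] = {}
        alleles: list[str] = [refb]
        for name, (h1, h2) in samples.items():
            a1 = haps[h1].get(p, refb)
            a2 = haps[h2].get(p, refb)
            per_sample[name] = (a1, a2)
            for a in (a1, a2):
                if a not in alleles:
                    alleles.append(a)
        if len(alleles) == 1:
            continue
        idx = {a: i for i, a in enumerate(alleles)}
        gts = {n: (idx[a1], idx[a2]) for n, (a1, a2) in per_sample.items()}
        dp = {n: int(rng.poisson(mean_depth)) + 8 for n in samples}
        gq = {n: 99 for n in samples}
        records.append(VariantRecord(CHROM, p + 1, refb, alleles[1:], gts, dp, gq))
    # group-fixed indels: male het, female hom-ref, others hom-ref
    g_of = cohort.config.group_of_strain()
    for group, indels in cohort.group_indels.items():
        carriers = {f"{s}_M" for s, g in g_of.items() if g == group}
        for r in indels:
            gts = {n: ((0, 1) if n in carriers else (0, 0)) for n in samples}
            dp = {n: int(rng.poisson(mean_depth)) + 8 for n in samples}
            records.append(
                VariantRecord(CHROM, r.pos, r.ref, [r.alt], gts, dp, {n: 99 for n in samples},
                              is_indel=True)
            )
    records.sort(key=lambda r: (r.pos, r.is_indel))
    return records


# ---------------------------------------------------------------------------
# allele-specific count tables
# ---------------------------------------------------------------------------

def simulate_allele_counts(config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           gene_names: list[str] | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene DNA (1:1) and RNA (true-ratio) allele counts, Poisson sampled.

    Each allele's count is Poisson with mean chosen so the X:Y mean ratio is
    1 for DNA and the gene's configured ratio for RNA, while the total mean
    per gene stays at twice the configured depth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if gene_names is None:
        gene_names = [f"gene{i:04d}" for i in range(config.n_genes)]
    if config.dna_depth <= 0 or config.rna_depth <= 0:
        raise ValueError("depths must be positive")
    rows_dna, rows_rna = [], []
    for i, gene in enumerate(gene_names):
        r = config.ratio_for_gene(gene, i)
        if r <= 0:
            raise ValueError(f"ratio for {gene} must be positive")
        dx = int(rng.poisson(config.dna_depth))
        dy = int(rng.poisson(config.dna_depth))
        rx = int(rng.poisson(config.rna_depth * 2.0 * r / (1.0 + r)))
        ry = int(rng.poisson(config.rna_depth * 2.0 / (1.0 + r)))
        rows_dna.append((gene, dx, dy))
        rows_rna.append((gene, rx, ry))
    dna = pd.DataFrame(rows_dna, columns=["gene", "count_x", "count_y"])
    rna = pd.DataFrame(rows_rna, columns=["gene", "count_x", "count_y"])
    return dna, rna


# ---------------------------------------------------------------------------
# tissue expression matrix
# ---------------------------------------------------------------------------

def simulate_tissue_matrix(config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """RPKM-like genes x tissues matrix plus true tissue-bias labels.

    Biased genes are expressed at 10x the baseline in one focal tissue
    (tau = 0.9 at zero noise); unbiased genes are uniform (tau = 0).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if config.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if config.tissue_noise < 0:
        raise ValueError("noise must be non-negative")
    tissues = [f"tissue{t}" for t in range(config.n_tissues)]
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    n_biased = int(round(config.tissue_biased_fraction * config.n_genes))
    biased_idx = set(rng.choice(config.n_genes, size=n_biased, replace=False).tolist())
    mat = np.full((config.n_genes, config.n_tissues), 5.0)
    labels: dict[str, str | None] = {}
    for i, gene in enumerate(genes):
        if i in biased_idx:
            focal = int(rng.integers(0, config.n_tissues))
            mat[i, :] = 1.0
            mat[i, focal] = 10.0
            labels[gene] = tissues[focal]
        else:
            labels[gene] = None
    if config.tissue_noise > 0:
        mat *= np.exp(rng.normal(0.0, config.tissue_noise, size=mat.shape))
    expr = pd.DataFrame(mat, index=genes, columns=tissues)
    return expr, labels
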