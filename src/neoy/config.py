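"""Simulation configuration objects and JSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class YGroupConfig:
    """One clonally evolving neo-Y group.

    ``recomb_stop_kya`` is the time (kya) at which the group's founder
    haplotype stopped recombining; after that the group accumulates
    group-fixed substitutions and indels clonally.  ``breakpoints`` are
    0-based positions where the founder mosaic switches neo-X donor.
    """

    name: str
    n_strains: int
    recomb_stop_kya: float
    breakpoints: list[int] = field(default_factory=list)


@dataclass
class SimulationConfig:
    chromosome_length: int = 1_000_000
    n_genes: int = 20
    gene_length: int = 900  # bp, must be a multiple of 3 (single-CDS genes)
    mu: float = 2e-5  # substitutions per bp per kyr on clonal neo-Y lineages
    indel_rate: float = 2e-7  # indels per bp per kyr on clonal neo-Y lineages
    theta: float = 0.008  # expected pairwise diversity among neo-X haplotypes
    species_split_kya: float = 250.0
    y_groups: list[YGroupConfig] = field(
        default_factory=lambda: [
            YGroupConfig("Y1", 3, 106.8, [400_000]),
            YGroupConfig("Y2", 3, 89.6, [150_000, 700_000]),
            YGroupConfig("Y3", 3, 135.2, [550_000]),
        ]
    )
    nasuta_block: tuple[int, int] = (900_000, 1_000_000)
    n_neoX: int = 12
    n_outgroup: int = 3
    # probability that a founder mosaic segment retains the shared proto-Y
    # lineage instead of a sampled neo-X donor
    proto_donor_prob: float = 0.5
    ase_ratios: dict[str, float] | float = 1.0
    dna_depth: float = 100.0
    rna_depth: float = 100.0
    n_tissues: int = 6
    tissue_biased_fraction: float = 0.3
    tissue_noise: float = 0.1
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if self.theta < 0 or self.mu < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_neoX < 2:
            raise ValueError("need at least 2 neo-X haplotypes")
        n_strains = sum(g.n_strains for g in self.y_groups)
        if n_strains == 0:
            raise ValueError("at least one neo-Y strain required")
        if self.n_neoX < n_strains:
            raise ValueError("n_neoX must cover one haplotype per neo-Y strain")
        for g in self.y_groups:
            if g.n_strains <= 0:
                raise ValueError(f"group {g.name} has no strains")
            if not g.recomb_stop_kya < self.species_split_kya:
                raise ValueError(
                    f"group {g.name}: recomb_stop_kya must precede the species split"
                )
            bps = list(g.breakpoints)
            if bps != sorted(set(bps)):
                raise ValueError(f"group {g.name}: breakpoints must strictly increase")
            if any(not (0 <= b < self.chromosome_length) for b in bps):
                raise ValueError(f"group {g.name}: breakpoints outside chromosome")
        s, e = self.nasuta_block
        if not (0 <= s < e <= self.chromosome_length):
            raise ValueError("nasuta_block outside chromosome")
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a multiple of 3")

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["nasuta_block"] = list(self.nasuta_block)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["y_groups"] = [YGroupConfig(**g) for g in d.get("y_groups", [])]
        if "nasuta_block" in d:
            d["nasuta_block"] = tuple(d["nasuta_block"])
        return cls(**d)

    def ratio_for_gene(self, gene: str, index: int) -> float:
        if isinstance(self.ase_ratios, dict):
            return float(self.ase_ratios[gene])
        return float(self.ase_ratios)

    def strain_names(self) -> list[str]:
        names: list[str] = []
        for g in self.y_groups:
            for i in range(g.n_strains):
                names.append(f"{g.name}_s{i}")
        return names

    def group_of_strain(self) -> dict[str, str]:
        return {
            f"{g.name}_s{i}": g.name for g in self.y_groups for i in range(g.n_strains)
        }
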