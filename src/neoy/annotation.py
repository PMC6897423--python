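"""Minimal single-CDS gene models and GFF3 I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class GeneModel:
    """A gene with a single CDS spanning [start, end] (1-based, closed)."""

    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError("bad gene coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        """1-based position inside the CDS."""
        return self.start <= pos <= self.end

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a 1-based genomic position within the coding sequence."""
        if not self.contains(pos):
            raise ValueError(f"{pos} outside {self.name}")
        if self.strand == "+":
            return pos - self.start
        return self.end - pos


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.name}"
        lines.append(
            "\t".join(
                [g.chrom, "neoy", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
            )
        )
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    "neoy",
                    "CDS",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    "0",
                    f"ID={g.name}.cds;Parent={g.name}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9 or f[2] != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        name = attrs.get("Parent") or attrs.get("ID", "gene")
        genes.append(GeneModel(name, f[0], int(f[3]), int(f[4]), f[6]))
    return genes
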