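"""Plain-text VCF / FASTA readers and writers.

VCF writing is done directly (uncompressed, VCFv4.2 with GT:DP:GQ);
reading goes through :mod:`pysam` so external call sets are accepted
unmodified.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pysam

from neoy.simulate import VariantRecord

_HEADER = """##fileformat=VCFv4.2
##source=neoy
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(records: Iterable[VariantRecord], samples: list[str],
              path: str | Path, chrom: str = "neo", chrom_length: int = 0) -> None:
    lines = [_HEADER.format(chrom=chrom, length=chrom_length or 1).rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for r in records:
        fields = [
            r.chrom, str(r.pos), ".", r.ref, ",".join(r.alts) or ".", ".", "PASS", ".", "GT:DP:GQ",
        ]
        for s in samples:
            gt = r.genotypes.get(s)
            g = "./." if gt is None else f"{gt[0]}/{gt[1]}"
            fields.append(f"{g}:{r.depth.get(s, 0)}:{r.gq.get(s, 0)}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF into the internal record shape (GT, DP, GQ)."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = list(rec.alts or [])
            gts: dict[str, tuple[int, int]] = {}
            dp: dict[str, int] = {}
            gq: dict[str, int] = {}
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT")
                if alleles is None or any(a is None for a in alleles):
                    continue
                gts[s] = (alleles[0], alleles[1])
                dp[s] = int(call.get("DP") or 0)
                gq[s] = int(call.get("GQ") or 0)
            is_indel = any(len(a) != len(rec.ref) for a in alts)
            records.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, alts, gts, dp, gq, is_indel)
            )
    return records, samples


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
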