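"""File-format helpers: FASTA, FASTQ (Phred+33) and BED6.

Thin wrappers over Biopython parsers so the rest of the package deals in
plain dicts, tuples and dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality-string) per record."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(records: Iterable[tuple[str, str, str]],
                path: str | Path) -> int:
    """Write (title, seq, qual-string) triples; returns record count."""
    n = 0
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def phred_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def string_to_phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


@dataclass(frozen=True)
class BedInterval:
    """BED6 interval: 0-based half-open, explicit strand."""
    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "+"

    def overlaps(self, chrom: str, start: int, end: int,
                 strand: str | None = None) -> bool:
        if chrom != self.chrom:
            return False
        if strand is not None and strand != self.strand:
            return False
        return start < self.end and end > self.start


def read_bed(path: str | Path) -> list[BedInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(BedInterval(f[0], int(f[1]), int(f[2]),
                                   f[3] if len(f) > 3 else ".",
                                   float(f[4]) if len(f) > 4 else 0.0,
                                   f[5] if len(f) > 5 else "+"))
    return out


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                     f"\t{iv.score:g}\t{iv.strand}\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
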