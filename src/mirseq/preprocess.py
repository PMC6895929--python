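"""Raw FASTQ to clean small-RNA reads.

Order of operations per read: exact 3' adapter removal, 3' quality
trimming at a Phred threshold (default Q20), then a 17-35 nt inclusive
length filter.  Reads containing N are dropped.  Every input read is
accounted for exactly once in the returned statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .io import iter_fastq, string_to_phred, phred_to_string, write_fastq

MIN_LEN = 17
MAX_LEN = 35
Q_THRESHOLD = 20


@dataclass
class RawRead:
    id: str
    sequence: str
    qualities: list[int]
    adapter_trimmed: bool = False
    quality_trimmed: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length "
                             "mismatch")


@dataclass
class PreprocessStats:
    """Per-library accounting; total_raw equals the sum of all others."""
    total_raw: int = 0
    after_preprocessing: int = 0
    dropped_short: int = 0
    dropped_long: int = 0
    dropped_quality: int = 0   # empty after quality trim
    dropped_n: int = 0

    def check(self) -> None:
        total = (self.after_preprocessing + self.dropped_short
                 + self.dropped_long + self.dropped_quality + self.dropped_n)
        if total != self.total_raw:
            raise AssertionError("preprocessing counts do not conserve")

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def trim_adapter(read: RawRead, adapter: str, min_overlap: int = 4
                 ) -> RawRead:
    """Remove a 3' adapter by exact suffix/prefix overlap.

    The longest read suffix equal to an adapter prefix (>= min_overlap),
    or any full internal adapter occurrence, is removed together with
    its qualities.  No match leaves the read unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    seq = read.sequence
    cut = len(seq)
    pos = seq.find(adapter)
    if pos >= 0:
        cut = pos
    else:
        max_k = min(len(adapter), len(seq))
        for k in range(max_k, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    if cut == len(seq):
        return read
    return replace(read, sequence=seq[:cut], qualities=read.qualities[:cut],
                   adapter_trimmed=True)


def quality_trim_3prime(read: RawRead, q_threshold: int = Q_THRESHOLD
                        ) -> RawRead:
    """Trim from the 3' end until the terminal base reaches the threshold."""
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    quals = read.qualities
    cut = len(quals)
    while cut > 0 and quals[cut - 1] < q_threshold:
        cut -= 1
    if cut == len(quals):
        return read
    return replace(read, sequence=read.sequence[:cut],
                   qualities=quals[:cut], quality_trimmed=True)


def length_filter(reads: Iterable[RawRead], min_len: int = MIN_LEN,
                  max_len: int = MAX_LEN,
                  stats: PreprocessStats | None = None
                  ) -> Iterator[RawRead]:
    """Pass reads with length in [min_len, max_len] inclusive."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    stats = stats if stats is not None else PreprocessStats()
    for read in reads:
        n = len(read.sequence)
        if n < min_len:
            stats.dropped_short += 1
        elif n > max_len:
            stats.dropped_long += 1
        else:
            stats.after_preprocessing += 1
            yield read


def preprocess_reads(reads: Iterable[RawRead], adapter: str,
                     q_threshold: int = Q_THRESHOLD,
                     min_len: int = MIN_LEN, max_len: int = MAX_LEN,
                     min_overlap: int = 4
                     ) -> tuple[list[RawRead], PreprocessStats]:
    """Adapter -> quality -> length, with conserving statistics."""
    stats = PreprocessStats()

    def staged() -> Iterator[RawRead]:
        for read in reads:
            stats.total_raw += 1
            if "N" in read.sequence:
                stats.dropped_n += 1
                continue
            read = trim_adapter(read, adapter, min_overlap)
            read = quality_trim_3prime(read, q_threshold)
            if not read.sequence:
                stats.dropped_quality += 1
                continue
            yield read

    clean = list(length_filter(staged(), min_len, max_len, stats))
    stats.check()
    return clean, stats


def preprocess_library(fastq_path: str | Path, adapter: str,
                       q_threshold: int = Q_THRESHOLD,
                       out_path: str | Path | None = None,
                       min_len: int = MIN_LEN, max_len: int = MAX_LEN
                       ) -> tuple[Path, PreprocessStats]:
    """Preprocess one FASTQ file; write the clean Phred+33 FASTQ."""
    fastq_path = Path(fastq_path)
    out_path = Path(out_path) if out_path is not None else \
        fastq_path.with_name(fastq_path.stem + ".clean.fastq")

    def raw_reads() -> Iterator[RawRead]:
        it = iter_fastq(fastq_path)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {i} in "
                                 f"{fastq_path}: {exc}") from exc
            yield RawRead(title, seq.upper(), string_to_phred(qual))
            i += 1

    clean, stats = preprocess_reads(raw_reads(), adapter, q_threshold,
                                    min_len, max_len)
    write_fastq(((r.id, r.sequence, phred_to_string(r.qualities))
                 for r in clean), out_path)
    return out_path, stats
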