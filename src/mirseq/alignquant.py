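"""Two-pass read alignment, class accounting and count matrices.

Pass 1 aligns each clean read end-to-end (ungapped, <= max_mismatch
substitutions) against the mature-miRNA, tRNA, rRNA and adapter
references via a k-mer seed index with pigeonhole-complete seeding.
Reads left unmapped go to the genome (both strands); genome hits that
fall inside annotated miRNA loci are credited to that miRNA (the count
"adjustment"), and the remaining genome hits feed novel-miRNA discovery.

Accounting reproduces the library-summary layout of a standard small
RNA-seq run: mapped_total = miRNA + tRNA + rRNA + adapter, percentages
against the post-preprocessing read count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .io import BedInterval, revcomp
from .preprocess import PreprocessStats

CLASS_PRIORITY = ("miRNA", "tRNA", "rRNA", "adapter")


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# k-mer index and ungapped alignment
# --------------------------------------------------------------------------

@dataclass
class KmerIndex:
    """Exact k-mer postings over a set of (oriented) reference sequences."""
    k: int
    refs: dict[str, str]                  # forward sequences
    both_strands: bool = False
    postings: dict[str, list[tuple[str, int, str]]] = field(
        default_factory=dict, repr=False)
    oriented: dict[tuple[str, str], str] = field(
        default_factory=dict, repr=False)


def build_kmer_index(references: dict[str, str], k: int,
                     both_strands: bool = False) -> KmerIndex:
    """Index every length-k substring (and the reverse complement when
    both_strands) of every reference."""
    for name, seq in references.items():
        if len(seq) < k:
            raise ValueError(f"reference {name!r} shorter than k={k}")
    idx = KmerIndex(k, dict(references), both_strands)
    post: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for name, seq in references.items():
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", revcomp(seq)))
        for strand, s in strands:
            idx.oriented[(name, strand)] = s
            for off in range(len(s) - k + 1):
                post[s[off:off + k]].append((name, off, strand))
    idx.postings = dict(post)
    return idx


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_id: str
    start: int        # 0-based offset on the forward reference strand
    strand: str
    mismatches: int
    length: int
    cls: str = "unknown"


def _hamming(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def align_read(read_seq: str, index: KmerIndex, max_mismatch: int = 1,
               read_id: str = "") -> list[AlignmentHit]:
    """All end-to-end placements of the read with <= max_mismatch.

    Seeds are max_mismatch+1 non-overlapping k-mers; by the pigeonhole
    principle this finds every qualifying placement provided
    k <= floor(len(read) / (max_mismatch + 1)).
    """
    L = len(read_seq)
    k = index.k
    if L < k:
        return []
    n_seeds = max_mismatch + 1
    if k * n_seeds > L:
        # fall back to every overlapping seed position (still complete
        # only when at least one seed window is mismatch-free)
        seed_positions = range(0, L - k + 1)
    else:
        seed_positions = [min(i * k, L - k) for i in range(n_seeds)]
    candidates: set[tuple[str, int, str]] = set()
    for sp in seed_positions:
        for name, off, strand in index.postings.get(
                read_seq[sp:sp + k], ()):
            start = off - sp
            if start >= 0:
                candidates.add((name, start, strand))
    hits = []
    for name, start, strand in candidates:
        ref = index.oriented[(name, strand)]
        if start + L > len(ref):
            continue
        mm = _hamming(read_seq, ref[start:start + L], max_mismatch)
        if mm <= max_mismatch:
            fwd_start = start if strand == "+" else len(ref) - start - L
            hits.append(AlignmentHit(read_id, name, fwd_start, strand,
                                     mm, L))
    hits.sort(key=lambda h: (h.mismatches, h.ref_id, h.start, h.strand))
    return hits


# --------------------------------------------------------------------------
# classification and counting
# --------------------------------------------------------------------------

@dataclass
class GenomeHit:
    """A genome placement retained for novel-miRNA discovery."""
    library: str
    read_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class LibrarySummary:
    library: str
    total_raw: int
    after_preprocessing: int
    mapped_total: int
    mapped_mirna: int
    mapped_trna: int
    mapped_rrna: int
    mapped_adapter: int
    expressed_mirnas_ge1: int = 0
    expressed_mirnas_ge3: int = 0

    def percentage(self, count: int, ndigits: int = 2) -> float | None:
        if self.after_preprocessing == 0:
            return None
        return round_half_up(100.0 * count / self.after_preprocessing,
                             ndigits)

    def percentages(self) -> dict[str, float | None]:
        return {
            "mapped_total": self.percentage(self.mapped_total),
            "mapped_mirna": self.percentage(self.mapped_mirna),
            "mapped_trna": self.percentage(self.mapped_trna),
            "mapped_rrna": self.percentage(self.mapped_rrna),
            "mapped_adapter": self.percentage(self.mapped_adapter, 4),
        }

    def check(self) -> None:
        total = (self.mapped_mirna + self.mapped_trna + self.mapped_rrna
                 + self.mapped_adapter)
        if total != self.mapped_total:
            raise AssertionError("mapped classes do not sum to mapped_total")


def summarize_library(library: str, stats: PreprocessStats,
                      class_counts: dict[str, int],
                      expressed_ge1: int = 0, expressed_ge3: int = 0
                      ) -> LibrarySummary:
    """Assemble the per-library summary from preprocessing stats and
    integer per-class mapped-read counts."""
    counts = {c: int(class_counts.get(c, 0)) for c in CLASS_PRIORITY}
    summary = LibrarySummary(
        library=library,
        total_raw=stats.total_raw,
        after_preprocessing=stats.after_preprocessing,
        mapped_total=sum(counts.values()),
        mapped_mirna=counts["miRNA"],
        mapped_trna=counts["tRNA"],
        mapped_rrna=counts["rRNA"],
        mapped_adapter=counts["adapter"],
        expressed_mirnas_ge1=expressed_ge1,
        expressed_mirnas_ge3=expressed_ge3,
    )
    summary.check()
    return summary


@dataclass
class CountMatrix:
    """miRNA x library counts with optional normalized layers."""
    raw: pd.DataFrame                       # float (fractional multimapping)
    mapped_totals: dict[str, int] = field(default_factory=dict)
    size_factors: dict[str, float] = field(default_factory=dict)
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def rounded(self) -> pd.DataFrame:
        """Integer counts for reporting (fractional assignments rounded)."""
        return self.raw.round(0).astype(int)


def normalize_counts(matrix: CountMatrix, mode: str) -> CountMatrix:
    """Add a normalized layer: RPM, size_factor or zscore.

    RPM = 1e6 * count / mapped reads of the library; size_factor divides
    by precomputed size factors; zscore row-standardizes the last layer
    added (or RPM), mapping constant rows to zero.
    """
    if mode == "RPM":
        totals = pd.Series({c: matrix.mapped_totals.get(c, 0)
                            for c in matrix.raw.columns}, dtype=float)
        if (totals <= 0).any():
            raise ValueError("RPM requires positive mapped totals "
                             "for every library")
        matrix.layers["RPM"] = 1e6 * matrix.raw / totals
    elif mode == "size_factor":
        if not matrix.size_factors:
            raise ValueError("size factors not set")
        sf = pd.Series(matrix.size_factors, dtype=float)
        if (sf <= 0).any():
            raise ValueError("size factors must be positive")
        matrix.layers["size_factor"] = matrix.raw / sf
    elif mode == "zscore":
        base = matrix.layers.get("RPM", matrix.raw)
        mu = base.mean(axis=1)
        sd = base.std(axis=1, ddof=0)
        z = base.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        matrix.layers["zscore"] = z.fillna(0.0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return matrix


def _locus_for_hit(hit_start: int, hit_end: int, chrom: str, strand: str,
                   loci: list[BedInterval], min_overlap: float
                   ) -> list[BedInterval]:
    length = hit_end - hit_start
    out = []
    for iv in loci:
        if iv.chrom != chrom or iv.strand != strand:
            continue
        ov = min(hit_end, iv.end) - max(hit_start, iv.start)
        if ov >= min_overlap * length:
            out.append(iv)
    return out


def classify_and_count(libraries: dict[str, list[tuple[str, str]]],
                       mature_ref: dict[str, str],
                       trna_ref: dict[str, str],
                       rrna_ref: dict[str, str],
                       adapter_seq: str,
                       genome: dict[str, str],
                       known_loci: list[BedInterval],
                       max_mismatch: int = 1,
                       k: int = 8,
                       min_locus_overlap: float = 0.9,
                       ) -> tuple[dict[str, dict[str, int]], CountMatrix,
                                  list[GenomeHit]]:
    """Classify every clean read of every library exactly once.

    `libraries` maps library name -> list of (read_id, sequence).
    Returns per-library class counts (including 'genome' and 'unmapped'),
    the miRNA count matrix, and unannotated genome hits for discovery.
    """
    for name, ref in (("mature", mature_ref), ("genome", genome)):
        if not ref:
            raise ValueError(f"{name} reference is empty")
    ref_indexes: list[tuple[str, KmerIndex]] = []
    for cls, refs in (("miRNA", mature_ref), ("tRNA", trna_ref),
                      ("rRNA", rrna_ref)):
        if refs:
            ref_indexes.append((cls, build_kmer_index(refs, k)))
    if adapter_seq and len(adapter_seq) >= k:
        ref_indexes.append(
            ("adapter", build_kmer_index({"adapter": adapter_seq}, k)))
    genome_index = build_kmer_index(genome, k, both_strands=True)
    mirna_loci = [iv for iv in known_loci]

    lib_names = sorted(libraries)
    counts = pd.DataFrame(0.0, index=sorted(mature_ref),
                          columns=lib_names)
    class_counts: dict[str, dict[str, int]] = {
        lib: defaultdict(int) for lib in lib_names}
    genome_hits: list[GenomeHit] = []

    for lib in lib_names:
        for read_id, seq in libraries[lib]:
            # pass 1: the four reference sets
            best_cls = None
            best_hits: list[AlignmentHit] = []
            best_mm = max_mismatch + 1
            for cls, index in ref_indexes:
                hits = align_read(seq, index, max_mismatch, read_id)
                if hits and hits[0].mismatches < best_mm:
                    best_cls, best_hits = cls, hits
                    best_mm = hits[0].mismatches
            if best_cls is not None:
                class_counts[lib][best_cls] += 1
                if best_cls == "miRNA":
                    top = [h for h in best_hits
                           if h.mismatches == best_mm]
                    ids = sorted({h.ref_id for h in top})
                    for rid in ids:
                        counts.loc[rid, lib] += 1.0 / len(ids)
                continue
            # pass 2: genome
            ghits = align_read(seq, genome_index, max_mismatch, read_id)
            if not ghits:
                class_counts[lib]["unmapped"] += 1
                continue
            gmm = ghits[0].mismatches
            top = [h for h in ghits if h.mismatches == gmm]
            assigned = False
            matched_ids: set[str] = set()
            for h in top:
                loci = _locus_for_hit(h.start, h.start + h.length,
                                      h.ref_id, h.strand, mirna_loci,
                                      min_locus_overlap)
                matched_ids.update(iv.name for iv in loci)
            if matched_ids:
                # the adjustment: genome hit inside a known miRNA locus
                class_counts[lib]["miRNA"] += 1
                for rid in sorted(matched_ids):
                    if rid in counts.index:
                        counts.loc[rid, lib] += 1.0 / len(matched_ids)
                assigned = True
            if not assigned:
                class_counts[lib]["genome"] += 1
                h = top[0]
                genome_hits.append(GenomeHit(
                    lib, read_id, seq, h.ref_id, h.start,
                    h.start + h.length, h.strand, h.mismatches))

    mapped_totals = {
        lib: sum(class_counts[lib][c] for c in CLASS_PRIORITY)
        for lib in lib_names}
    matrix = CountMatrix(raw=counts, mapped_totals=mapped_totals)
    return ({lib: dict(c) for lib, c in class_counts.items()},
            matrix, genome_hits)


def expressed_mirna_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Per-library numbers of miRNAs with >= 1 and >= 3 reads."""
    rounded = matrix.rounded()
    return pd.DataFrame({
        "expressed_ge1": (rounded >= 1).sum(axis=0),
        "expressed_ge3": (rounded >= 3).sum(axis=0),
    })
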