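"""Novel miRNA discovery from unannotated genome-mapped reads.

Reads mapping to the genome outside annotated miRNA loci are merged
into same-strand clusters; clusters with at least four reads summed
across samples are excised into two candidate precursor windows (mature
pinned near the 5' or the 3' end), folded by free-energy minimisation,
and kept when the structure is a single stem-loop with delta-G <= -20
kcal/mol whose mature arm is predominantly paired against the opposite
arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignquant import GenomeHit
from .fold import (EnergyModel, DEFAULT_MODEL, fold_mfe, parse_dotbracket,
                   count_hairpin_loops)
from .io import BedInterval, revcomp

MIN_CLUSTER_READS = 4
MFE_THRESHOLD = -20.0
MIN_MATURE_PAIRED = 0.75
DEFAULT_FLANK = 70


@dataclass
class ReadCluster:
    chrom: str
    start: int                     # envelope of all merged reads
    end: int
    strand: str
    count: int
    consensus: str                 # most frequent read sequence
    consensus_start: int = -1      # span of the modal read (the putative
    consensus_end: int = -1        # mature sequence)
    samples: dict[str, int] = field(default_factory=dict)
    annotation_overlap: str = ""   # non-miRNA annotation touching the locus


@dataclass
class HairpinCandidate:
    cluster: ReadCluster
    precursor: str
    window_start: int
    window_end: int
    arm: str                       # mature pinned at '5p' or '3p'
    mature_offset: int
    mature_length: int
    structure: str = ""
    delta_g: float = 0.0
    mature_paired_fraction: float = 0.0
    n_hairpin_loops: int = 0
    mfe_pass: bool = False
    single_hairpin: bool = False
    mature_in_stem: bool = False
    truncated: bool = False

    @property
    def overall_pass(self) -> bool:
        return self.mfe_pass and self.single_hairpin and self.mature_in_stem


def cluster_unannotated_reads(hits: list[GenomeHit],
                              known_loci: list[BedInterval],
                              min_count: int = MIN_CLUSTER_READS,
                              merge_gap: int = 10,
                              other_annotations: list[BedInterval]
                              | None = None) -> list[ReadCluster]:
    """Merge same-strand hits within merge_gap into read clusters.

    Clusters overlapping a known miRNA locus are discarded; overlap with
    any other supplied annotation (tRNA/rRNA loci) is only flagged.
    Clusters with summed count across samples below min_count are
    dropped.
    """
    keyed = sorted(hits, key=lambda h: (h.chrom, h.strand, h.start, h.end))
    clusters: list[list[GenomeHit]] = []
    for h in keyed:
        if (clusters and clusters[-1][0].chrom == h.chrom
                and clusters[-1][0].strand == h.strand
                and h.start <= max(x.end for x in clusters[-1]) + merge_gap):
            clusters[-1].append(h)
        else:
            clusters.append([h])

    out = []
    for group in clusters:
        if len(group) < min_count:
            continue
        start = min(h.start for h in group)
        end = max(h.end for h in group)
        chrom, strand = group[0].chrom, group[0].strand
        if any(iv.overlaps(chrom, start, end) for iv in known_loci):
            continue
        seq_counts: dict[tuple[str, int, int], int] = {}
        samples: dict[str, int] = {}
        for h in group:
            key = (h.sequence, h.start, h.end)
            seq_counts[key] = seq_counts.get(key, 0) + 1
            samples[h.library] = samples.get(h.library, 0) + 1
        cseq, cstart, cend = max(seq_counts,
                                 key=lambda k: (seq_counts[k], k))
        overlap = ""
        for iv in other_annotations or []:
            if iv.overlaps(chrom, start, end):
                overlap = iv.name
                break
        out.append(ReadCluster(chrom, start, end, strand, len(group),
                               cseq, cstart, cend, samples, overlap))
    return out


def extract_precursor_windows(cluster: ReadCluster,
                              genome: dict[str, str],
                              flank: int = DEFAULT_FLANK
                              ) -> list[HairpinCandidate]:
    """Two precursor windows per cluster, mature near either end.

    Window A pins the mature at the 5' arm (short upstream pad, long
    downstream flank), window B at the 3' arm.  Minus-strand windows are
    reverse-complemented; coordinates stay genomic (forward strand).
    """
    chrom_seq = genome.get(cluster.chrom)
    if chrom_seq is None or cluster.start >= len(chrom_seq):
        raise ValueError(f"cluster outside genome: {cluster.chrom}:"
                         f"{cluster.start}-{cluster.end}")
    pad = 10
    mstart = (cluster.consensus_start if cluster.consensus_start >= 0
              else cluster.start)
    mend = (cluster.consensus_end if cluster.consensus_end >= 0
            else cluster.end)
    mat_len = mend - mstart
    plans = []
    if cluster.strand == "+":
        plans.append(("5p", mstart - pad, mend + flank))
        plans.append(("3p", mstart - flank, mend + pad))
    else:
        # 5' of a minus-strand mature is at the higher genome coordinate
        plans.append(("5p", mstart - flank, mend + pad))
        plans.append(("3p", mstart - pad, mend + flank))
    out = []
    for arm, ws, we in plans:
        truncated = ws < 0 or we > len(chrom_seq)
        ws_c, we_c = max(0, ws), min(len(chrom_seq), we)
        seq = chrom_seq[ws_c:we_c]
        if cluster.strand == "+":
            mat_off = mstart - ws_c
        else:
            seq = revcomp(seq)
            mat_off = we_c - mend
        out.append(HairpinCandidate(cluster, seq, ws_c, we_c, arm,
                                    mat_off, mat_len, truncated=truncated))
    return out


def _mature_branch(pairs: list[int], i0: int, i1: int
                   ) -> tuple[int, int] | None:
    """Largest helix branch holding the mature whose subtree is a
    single stem-loop; falls back to the outermost mature branch.

    Excision windows carry random flank that can fold a detached side
    hairpin inside the same outer helix; descending to the largest
    single-hairpin branch isolates the putative precursor stem.
    """
    n = len(pairs)
    mature_len = i1 - i0
    best_single = None
    outer = None
    k = 0
    # top-level branches (for the fallback)
    while k < n:
        if pairs[k] > k:
            j = pairs[k]
            inside = max(0, min(i1, j + 1) - max(i0, k))
            if outer is None or inside > outer[0]:
                outer = (inside, k, j)
            k = j + 1
        else:
            k += 1
    # every branch, any nesting depth
    for i in range(n):
        j = pairs[i]
        if j <= i:
            continue
        inside = max(0, min(i1, j + 1) - max(i0, i))
        if inside < mature_len / 2:
            continue
        sub = pairs[i:j + 1]
        loops = 0
        for a in range(len(sub)):
            b = sub[a] - i
            if 0 <= b < len(sub) and b > a:
                if all(sub[c] < i for c in range(a + 1, b)):
                    loops += 1
        if loops == 1:
            span = j - i
            if best_single is None or span > best_single[0]:
                best_single = (span, i, j)
    if best_single is not None:
        return best_single[1], best_single[2]
    if outer is None or outer[0] < mature_len / 2:
        return None
    return outer[1], outer[2]


def evaluate_candidate(candidate: HairpinCandidate,
                       model: EnergyModel | None = None,
                       mfe_threshold: float = MFE_THRESHOLD,
                       min_mature_paired: float = MIN_MATURE_PAIRED,
                       trim_to_hairpin: bool = True) -> HairpinCandidate:
    """Fold the precursor window and apply the three discovery criteria.

    The excision window carries arbitrary flanking sequence, so the
    candidate is first trimmed to the outermost stem-loop branch that
    holds the mature (the putative precursor) and re-folded.  Criteria:
    mfe_pass (delta-G <= threshold, inclusive), single_hairpin (exactly
    one hairpin loop), and mature_in_stem (at least min_mature_paired of
    the mature bases paired, every partner on the opposite arm).
    """
    model = model or DEFAULT_MODEL
    i0, i1 = candidate.mature_offset, (candidate.mature_offset
                                       + candidate.mature_length)
    if i0 < 0 or i1 > len(candidate.precursor):
        raise ValueError("mature coordinates outside precursor window")
    structure, dg = fold_mfe(candidate.precursor, model)

    if trim_to_hairpin:
        for _ in range(3):
            branch = _mature_branch(parse_dotbracket(structure), i0, i1)
            if branch is None or branch[1] - branch[0] + 1 < 10 \
                    or branch == (0, len(candidate.precursor) - 1):
                break
            bi, bj = branch
            win_len = len(candidate.precursor)
            candidate.precursor = candidate.precursor[bi:bj + 1]
            candidate.mature_offset = max(0, i0 - bi)
            i0 = candidate.mature_offset
            i1 = min(len(candidate.precursor),
                     i0 + candidate.mature_length)
            if candidate.cluster.strand == "+":
                candidate.window_start += bi
                candidate.window_end -= win_len - 1 - bj
            else:
                candidate.window_end -= bi
                candidate.window_start += win_len - 1 - bj
            structure, dg = fold_mfe(candidate.precursor, model)
            if count_hairpin_loops(structure) <= 1:
                break

    candidate.structure = structure
    candidate.delta_g = dg
    candidate.n_hairpin_loops = count_hairpin_loops(structure)
    candidate.mfe_pass = dg <= mfe_threshold
    candidate.single_hairpin = candidate.n_hairpin_loops == 1

    pairs = parse_dotbracket(structure)
    paired = [k for k in range(i0, i1) if pairs[k] >= 0]
    frac = len(paired) / max(1, candidate.mature_length)
    candidate.mature_paired_fraction = round(frac, 4)
    opposite = bool(paired) and all(p < i0 or p >= i1 for p in
                                    (pairs[k] for k in paired))
    candidate.mature_in_stem = frac >= min_mature_paired and opposite
    return candidate


def discover_novel(hits: list[GenomeHit],
                   known_loci: list[BedInterval],
                   genome: dict[str, str],
                   model: EnergyModel | None = None,
                   min_count: int = MIN_CLUSTER_READS,
                   flank: int = DEFAULT_FLANK,
                   mfe_threshold: float = MFE_THRESHOLD,
                   min_mature_paired: float = MIN_MATURE_PAIRED,
                   merge_gap: int = 10,
                   other_annotations: list[BedInterval] | None = None,
                   ) -> tuple[pd.DataFrame, list[HairpinCandidate]]:
    """Cluster -> excise -> fold -> evaluate; ranked candidate table.

    The best-scoring (lowest delta-G among passing, else lowest overall)
    window is kept per cluster.  The returned table has one row per
    cluster that passed all three criteria, ranked by delta-G.
    """
    clusters = cluster_unannotated_reads(hits, known_loci, min_count,
                                         merge_gap, other_annotations)
    kept: list[HairpinCandidate] = []
    for cluster in clusters:
        windows = [evaluate_candidate(c, model, mfe_threshold,
                                      min_mature_paired)
                   for c in extract_precursor_windows(cluster, genome,
                                                      flank)]
        windows.sort(key=lambda c: (not c.overall_pass, c.delta_g))
        kept.append(windows[0])

    rows = []
    for cand in kept:
        if not cand.overall_pass:
            continue
        c = cand.cluster
        mstart = c.consensus_start if c.consensus_start >= 0 else c.start
        mend = c.consensus_end if c.consensus_end >= 0 else c.end
        rows.append({
            "chrom": c.chrom, "mature_start": mstart,
            "mature_end": mend, "strand": c.strand,
            "cluster_start": c.start, "cluster_end": c.end,
            "read_count": c.count, "consensus": c.consensus,
            "window_start": cand.window_start,
            "window_end": cand.window_end,
            "delta_g": cand.delta_g,
            "mature_paired_fraction": cand.mature_paired_fraction,
            "annotation_overlap": c.annotation_overlap,
            **{f"reads_{lib}": n for lib, n in sorted(c.samples.items())},
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("delta_g").reset_index(drop=True)
        table.insert(0, "candidate_id",
                     [f"novel-cand-{i + 1}" for i in range(len(table))])
    return table, kept
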