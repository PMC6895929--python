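"""Seed-based miRNA target prediction on 3'UTR sequences.

A target site requires (i) a perfect Watson-Crick match of the miRNA
seed (bases 2-8 from the 5' end, no G:U) on the UTR, (ii) a weighted
local duplex alignment score at or above threshold (default 150), and
(iii) a duplex minimum free energy at or below threshold (default -20
kcal/mol).  Predicted targets are then paired with mRNA expression
calls: a (miRNA, gene) pair is consistent when the two move in opposite
directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fold import duplex_mfe as _duplex_mfe, EnergyModel
from .io import revcomp

SEED_START = 1   # 0-based: miRNA bases 2..8 inclusive
SEED_END = 8
SCORE_THRESHOLD = 150.0
MFE_THRESHOLD = -20.0

_RNA = str.maketrans("Tt", "Uu")


def _rna(seq: str) -> str:
    return seq.upper().translate(_RNA)


def _complementary(a: str, b: str) -> bool:
    return a + b in ("AU", "UA", "CG", "GC")


def _wobble(a: str, b: str) -> bool:
    return a + b in ("GU", "UG")


@dataclass
class ScoringScheme:
    """miRanda-style duplex alignment weights (unitless)."""
    match: float = 5.0
    wobble: float = 1.0       # G:U outside the seed only
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_weight: float = 4.0  # multiplies match score at seed positions

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 < match")


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_start: int          # 0-based half-open on the UTR
    site_end: int
    seed_start: int
    seed_end: int
    score: float
    delta_g: float
    score_pass: bool = False
    mfe_pass: bool = False

    @property
    def overall_pass(self) -> bool:
        return self.score_pass and self.mfe_pass


def find_seed_sites(mirna: str, utr: str) -> list[tuple[int, int]]:
    """All exact occurrences of the seed complement on the UTR.

    The seed is miRNA bases 2-8 (7 nt); the UTR must carry its exact
    reverse complement (T and U equivalent, no wobble).  Returns
    (start, end) half-open coordinates of each match.
    """
    mir = _rna(mirna)
    if len(mir) < SEED_END:
        raise ValueError("miRNA must be at least 8 nt")
    probe = _rna(revcomp(mir[SEED_START:SEED_END].replace("U", "T")))
    u = _rna(utr)
    out = []
    pos = u.find(probe)
    while pos >= 0:
        out.append((pos, pos + len(probe)))
        pos = u.find(probe, pos + 1)
    return out


def score_duplex(mirna: str, window: str,
                 scheme: ScoringScheme | None = None
                 ) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Best local duplex alignment of a miRNA against a UTR window.

    The miRNA is taken 3'->5' against the window 5'->3' so aligned
    positions can base-pair; complementary positions score `match`
    (times seed_weight inside the seed), G:U outside the seed scores
    `wobble`, everything else `mismatch`, with affine gaps.  Returns
    (score, miRNA span, window span) of the best local alignment; ties
    resolve toward the pairing (diagonal) state, i.e. fewer gaps.
    """
    scheme = scheme or ScoringScheme()
    mir = _rna(mirna)
    win = _rna(window)
    if len(win) < SEED_END - SEED_START:
        raise ValueError("window shorter than the seed")
    a = mir[::-1]          # a[i] is miRNA base L-i (3' end first)
    L, W = len(a), len(win)
    NEG = float("-inf")
    # Smith-Waterman with affine gaps: M pairs a[i-1] with win[j-1]
    M = [[0.0] * (W + 1) for _ in range(L + 1)]
    X = [[NEG] * (W + 1) for _ in range(L + 1)]   # gap in window
    Y = [[NEG] * (W + 1) for _ in range(L + 1)]   # gap in miRNA
    best, best_ij = 0.0, (0, 0)
    for i in range(1, L + 1):
        mir_pos = L - i          # 0-based position on the miRNA
        in_seed = SEED_START <= mir_pos < SEED_END
        for j in range(1, W + 1):
            x, y = a[i - 1], win[j - 1]
            if _complementary(x, y):
                s = scheme.match * (scheme.seed_weight if in_seed else 1.0)
            elif _wobble(x, y) and not in_seed:
                s = scheme.wobble
            else:
                s = scheme.mismatch
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1],
                       0.0)
            M[i][j] = prev + s
            X[i][j] = max(M[i - 1][j] + scheme.gap_open,
                          X[i - 1][j] + scheme.gap_extend)
            Y[i][j] = max(M[i][j - 1] + scheme.gap_open,
                          Y[i][j - 1] + scheme.gap_extend)
            if M[i][j] > best:
                best, best_ij = M[i][j], (i, j)
    # recover spans by retracing from the best cell
    i, j = best_ij
    state = "M"
    end_i, end_j = i, j
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] <= 0:
                break
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1],
                       0.0)
            if prev == 0.0 and M[i - 1][j - 1] != 0.0 \
                    and prev > max(X[i - 1][j - 1], Y[i - 1][j - 1]):
                i, j = i - 1, j - 1
                break
            if prev == M[i - 1][j - 1]:
                state = "M"
            elif prev == X[i - 1][j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
            if prev == 0.0:
                break
        elif state == "X":
            state = "M" if X[i][j] == M[i - 1][j] + scheme.gap_open else "X"
            i -= 1
        else:
            state = "M" if Y[i][j] == M[i][j - 1] + scheme.gap_open else "Y"
            j -= 1
    mir_span = (L - end_i, L - i)        # 0-based on the miRNA
    win_span = (j, end_j)
    return best, mir_span, win_span


def duplex_mfe(mirna: str, site_seq: str,
               model: EnergyModel | None = None) -> float:
    """Intermolecular duplex free energy (kcal/mol) of miRNA vs site."""
    return _duplex_mfe(mirna, site_seq, model)


def predict_targets(mirna_id: str, mirna: str, utrs: dict[str, str],
                    scheme: ScoringScheme | None = None,
                    score_threshold: float = SCORE_THRESHOLD,
                    mfe_threshold: float = MFE_THRESHOLD,
                    all_sites: bool = False,
                    model: EnergyModel | None = None) -> list[TargetSite]:
    """Seed search -> duplex score -> duplex MFE over a UTR set.

    A site passes iff score >= score_threshold and delta-G <=
    mfe_threshold (both inclusive).  By default the best passing site
    per transcript is returned; all_sites keeps every evaluated site.
    """
    scheme = scheme or ScoringScheme()
    mir = _rna(mirna)
    tail = len(mir) - SEED_END      # miRNA bases 3' of the seed
    out: list[TargetSite] = []
    for tid, utr in utrs.items():
        u = _rna(utr)
        sites: list[TargetSite] = []
        for s, e in find_seed_sites(mir, u):
            ws = max(0, s - tail - 8)
            we = min(len(u), e + 1)
            window = u[ws:we]
            score, _, win_span = score_duplex(mir, window, scheme)
            dg = duplex_mfe(mir, window, model)
            site = TargetSite(
                mirna_id, tid, ws + win_span[0], ws + win_span[1],
                s, e, score, dg,
                score_pass=score >= score_threshold,
                mfe_pass=dg <= mfe_threshold)
            sites.append(site)
        if all_sites:
            out.extend(sites)
        else:
            passing = [t for t in sites if t.overall_pass]
            if passing:
                out.append(max(passing, key=lambda t: (t.score, -t.delta_g)))
    return out


@dataclass
class AnticorrelatedPair:
    mirna_id: str
    gene_id: str
    mirna_direction: str     # up | down
    mrna_direction: str
    consistent: bool
    shared_target: bool = False   # gene targeted by more than one miRNA


def pair_expression(mirna_calls: dict[str, str],
                    mrna_calls: dict[str, str],
                    target_map: dict[str, list[str]]
                    ) -> list[AnticorrelatedPair]:
    """Anti-correlated (miRNA, target gene) pairs.

    `mirna_calls` and `mrna_calls` map ids to 'up'/'down'; `target_map`
    maps miRNA id -> predicted target gene ids.  Pairs are consistent
    when directions are opposite; genes hit by more than one calling
    miRNA are flagged.  Unknown ids are skipped (reported by returning
    no pair), never fatal.
    """
    gene_hits: dict[str, int] = {}
    for mir, genes in target_map.items():
        if mir not in mirna_calls:
            continue
        for g in genes:
            if g in mrna_calls:
                gene_hits[g] = gene_hits.get(g, 0) + 1
    out = []
    for mir, genes in sorted(target_map.items()):
        if mir not in mirna_calls:
            continue
        mdir = mirna_calls[mir]
        for g in sorted(set(genes)):
            if g not in mrna_calls:
                continue
            gdir = mrna_calls[g]
            out.append(AnticorrelatedPair(
                mir, g, mdir, gdir,
                consistent=(mdir != gdir and {mdir, gdir} == {"up", "down"}),
                shared_target=gene_hits.get(g, 0) > 1))
    return out


def sites_table(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna": t.mirna_id, "transcript": t.transcript_id,
        "site_start": t.site_start, "site_end": t.site_end,
        "seed_start": t.seed_start, "seed_end": t.seed_end,
        "score": t.score, "delta_g": t.delta_g,
        "pass": t.overall_pass} for t in sites])
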