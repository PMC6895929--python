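"""RNA secondary-structure prediction by free-energy minimisation.

Implements a Zuker-style O(n^3) dynamic program over a nearest-neighbor
energy model (helix stacks, hairpin/bulge/internal loop initiations and a
linear multiloop model; G:U wobbles allowed, no pseudoknots, no dangling
ends or coaxial stacking).  The same energy functions score an explicit
dot-bracket structure, so the minimum returned by the DP can be verified
by re-scoring its traceback.

Also provides a Nussinov maximum-pairing DP (used as an upper bound on
pair counts) and an intermolecular duplex MFE for miRNA:target sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import _energies as E

INF = math.inf

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _normalize(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid bases for folding: {sorted(bad)}")
    return s


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble."""
    return a + b in ("AU", "UA", "CG", "GC", "GU", "UG")


@dataclass
class EnergyModel:
    """Nearest-neighbor parameter set (kcal/mol).

    `stack[p1][p2]` is the energy of stacking pair p2 = (i+1, j-1) on the
    closing pair p1 = (i, j); loop tables give initiation penalties by
    unpaired length; the multiloop is scored a + b*branches + c*unpaired.
    """

    stack: dict = field(default_factory=lambda: E.STACK)
    min_hairpin: int = E.MIN_HAIRPIN
    max_interior: int = E.MAX_INTERIOR
    multi_a: float = E.MULTI_A
    multi_b: float = E.MULTI_B
    multi_c: float = E.MULTI_C

    def stack_energy(self, p1: str, p2: str) -> float:
        return self.stack[p1][p2]

    def hairpin(self, n: int) -> float:
        return E.hairpin_energy(n)

    def bulge(self, n: int) -> float:
        return E.bulge_energy(n)

    def internal(self, l1: int, l2: int) -> float:
        return E.internal_energy(l1, l2)


DEFAULT_MODEL = EnergyModel()


def _loop_energy(model: EnergyModel, seq: str, i: int, j: int,
                 k: int, l: int) -> float:
    """Energy of the loop closed by (i,j) with inner helix (k,l)."""
    l1, l2 = k - i - 1, j - l - 1
    if l1 + l2 > model.max_interior:
        return INF
    if l1 == 0 and l2 == 0:
        return model.stack_energy(seq[i] + seq[j], seq[k] + seq[l])
    if l1 == 0 or l2 == 0:
        return model.bulge(l1 + l2)
    return model.internal(l1, l2)


def fold_mfe(sequence: str, model: EnergyModel | None = None
             ) -> tuple[str, float]:
    """Minimum-free-energy nested structure of a single RNA strand.

    Returns (dot-bracket, delta-G in kcal/mol).  A sequence that cannot
    form any stabilising structure gets the open chain: ('.'*n, 0.0).
    """
    model = model or DEFAULT_MODEL
    seq = _normalize(sequence)
    n = len(seq)
    if n < 10 or n > 200:
        raise ValueError(f"sequence length {n} outside supported 10..200")

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]
    # traceback choices
    vtb: dict[tuple[int, int], tuple] = {}
    mtb: dict[tuple[int, int], tuple] = {}

    min_span = model.min_hairpin + 1
    for span in range(min_span, n):
        for i in range(0, n - span):
            j = i + span
            # --- V: (i, j) paired ---
            if can_pair(seq[i], seq[j]):
                best = model.hairpin(j - i - 1)
                choice = ("H",)
                # interior loops (incl. stacks and bulges)
                for k in range(i + 1, j - 1):
                    if k - i - 1 > model.max_interior:
                        break
                    lmin = max(k + model.min_hairpin + 1,
                               j - 1 - (model.max_interior - (k - i - 1)))
                    for l in range(j - 1, lmin - 1, -1):
                        if l <= k:
                            break
                        if V[k][l] == INF:
                            continue
                        e = _loop_energy(model, seq, i, j, k, l)
                        if e + V[k][l] < best:
                            best = e + V[k][l]
                            choice = ("I", k, l)
                # multiloop closed by (i, j)
                for k in range(i + 2, j - 2):
                    if WM[i + 1][k] == INF or WM[k + 1][j - 1] == INF:
                        continue
                    e = (model.multi_a + model.multi_b
                         + WM[i + 1][k] + WM[k + 1][j - 1])
                    if e < best:
                        best = e
                        choice = ("M", k)
                if best < INF:
                    V[i][j] = best
                    vtb[(i, j)] = choice
            # --- WM: segment inside a multiloop ---
            best = INF
            choice = None
            if V[i][j] < INF and V[i][j] + model.multi_b < best:
                best = V[i][j] + model.multi_b
                choice = ("B",)
            if WM[i + 1][j] + model.multi_c < best:
                best = WM[i + 1][j] + model.multi_c
                choice = ("L",)
            if WM[i][j - 1] + model.multi_c < best:
                best = WM[i][j - 1] + model.multi_c
                choice = ("R",)
            for k in range(i + 1, j):
                if WM[i][k] == INF or WM[k + 1][j] == INF:
                    continue
                if WM[i][k] + WM[k + 1][j] < best:
                    best = WM[i][k] + WM[k + 1][j]
                    choice = ("S", k)
            if choice is not None:
                WM[i][j] = best
                mtb[(i, j)] = choice

    # external loop
    W = [0.0] * (n + 1)  # W[j+1] = best energy of prefix 0..j
    wtb: list[tuple | None] = [None] * (n + 1)
    for j in range(n):
        best = W[j]
        choice = None
        for i in range(0, j):
            if V[i][j] < INF and W[i] + V[i][j] < best:
                best = W[i] + V[i][j]
                choice = ("P", i)
        W[j + 1] = best
        wtb[j + 1] = choice

    dg = W[n]
    if dg >= 0:
        return "." * n, 0.0

    pairs = [-1] * n

    def _trace_v(i: int, j: int) -> None:
        pairs[i], pairs[j] = j, i
        kind = vtb[(i, j)]
        if kind[0] == "H":
            return
        if kind[0] == "I":
            _trace_v(kind[1], kind[2])
            return
        k = kind[1]
        _trace_wm(i + 1, k)
        _trace_wm(k + 1, j - 1)

    def _trace_wm(i: int, j: int) -> None:
        kind = mtb[(i, j)]
        if kind[0] == "B":
            _trace_v(i, j)
        elif kind[0] == "L":
            _trace_wm(i + 1, j)
        elif kind[0] == "R":
            _trace_wm(i, j - 1)
        else:
            _trace_wm(i, kind[1])
            _trace_wm(kind[1] + 1, j)

    j = n
    while j > 0:
        ch = wtb[j]
        if ch is None:
            j -= 1
        else:
            _trace_v(ch[1], j - 1)
            j = ch[1]

    db = "".join("(" if pairs[x] > x else ")" if pairs[x] >= 0 else "."
                 for x in range(n))
    return db, round(dg, 10)


def parse_dotbracket(structure: str) -> list[int]:
    """Pair table: pairs[i] = partner index or -1.  Raises on imbalance."""
    stack: list[int] = []
    pairs = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"bad structure char {c!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return pairs


def score_structure(sequence: str, structure: str,
                    model: EnergyModel | None = None) -> float:
    """Free energy of an explicit structure under the same model as the DP."""
    model = model or DEFAULT_MODEL
    seq = _normalize(sequence)
    pairs = parse_dotbracket(structure)
    if len(pairs) != len(seq):
        raise ValueError("structure/sequence length mismatch")

    def branch_energy(i: int, j: int) -> float:
        children = []
        k = i + 1
        unpaired = 0
        while k < j:
            if pairs[k] > k:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            return model.hairpin(j - i - 1)
        if len(children) == 1:
            k, l = children[0]
            e = _loop_energy(model, seq, i, j, k, l)
            return e + branch_energy(k, l)
        e = (model.multi_a + model.multi_b * (1 + len(children))
             + model.multi_c * unpaired)
        return e + sum(branch_energy(k, l) for k, l in children)

    total = 0.0
    k = 0
    while k < len(seq):
        if pairs[k] > k:
            total += branch_energy(k, pairs[k])
            k = pairs[k] + 1
        else:
            k += 1
    return total


def nussinov_max_pairs(sequence: str, min_hairpin: int = E.MIN_HAIRPIN) -> int:
    """Maximum number of nested base pairs (Watson-Crick + G:U)."""
    seq = _normalize(sequence)
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_hairpin):
                if can_pair(seq[k], seq[j]):
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i][j] = best
    return dp[0][n - 1] if n else 0


def count_hairpin_loops(structure: str) -> int:
    """Number of hairpin loops (innermost closed loops) in a structure."""
    pairs = parse_dotbracket(structure)
    n_loops = 0
    for i, j in enumerate(pairs):
        if j > i:
            if all(pairs[k] == -1 for k in range(i + 1, j)):
                n_loops += 1
    return n_loops


def duplex_mfe(seq_a: str, seq_b: str,
               model: EnergyModel | None = None) -> float:
    """Intermolecular duplex minimum free energy (kcal/mol, <= 0).

    Both strands 5'->3'; the duplex is antiparallel.  Only stacks and
    bulge/internal loop penalties are scored (no intramolecular pairs,
    no initiation term), so two non-complementary strands score 0.
    """
    model = model or DEFAULT_MODEL
    a = _normalize(seq_a)
    b = _normalize(seq_b)
    if len(a) > 50 or len(b) > 50:
        raise ValueError("duplex strands must be <= 50 nt")
    u = b[::-1]
    n, m = len(a), len(u)
    # D[i][j]: best energy of a duplex whose 3'-most pair (on a) is (i, j)
    D = [[INF] * m for _ in range(n)]
    best_overall = 0.0
    for i in range(n):
        for j in range(m):
            if not can_pair(a[i], u[j]):
                continue
            best = 0.0  # start a new duplex at this pair
            for ip in range(max(0, i - model.max_interior - 1), i):
                for jp in range(max(0, j - model.max_interior - 1), j):
                    if D[ip][jp] == INF:
                        continue
                    l1, l2 = i - ip - 1, j - jp - 1
                    if l1 + l2 > model.max_interior:
                        continue
                    if l1 == 0 and l2 == 0:
                        e = model.stack_energy(a[ip] + u[jp], a[i] + u[j])
                    elif l1 == 0 or l2 == 0:
                        e = model.bulge(l1 + l2)
                    else:
                        e = model.internal(l1, l2)
                    if D[ip][jp] + e < best:
                        best = D[ip][jp] + e
            D[i][j] = best
            if best < best_overall:
                best_overall = best
    return round(best_overall, 10)
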