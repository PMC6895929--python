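"""Nearest-neighbor free-energy parameters (kcal/mol, 37 degC).

Watson-Crick stack values follow the published Turner nearest-neighbor
set; G:U-containing stacks are approximate (wobble stacks are clamped
at <= 0 so that helix extension is never destabilising in this model).
Loop initiation tables are extended beyond the tabulated lengths with
the Jacobson-Stockmayer logarithmic term.
"""

from __future__ import annotations

import math

RT = 0.6163  # kcal/mol at 310.15 K

# Base pairs are encoded as two-letter strings, 5' base of the closing
# strand first.  Order used for documentation only.
PAIRS = ("AU", "CG", "GC", "UA", "GU", "UG")

# STACK[p1][p2]: helix stack where p1 = (i, j) closes and p2 = (i+1, j-1)
# sits on top of it.  Symmetric under p1,p2 -> rev(p2),rev(p1).
STACK: dict[str, dict[str, float]] = {
    "AU": {"AU": -0.93, "CG": -2.24, "GC": -2.08, "UA": -1.10,
           "GU": -0.60, "UG": -1.40},
    "CG": {"AU": -2.11, "CG": -3.26, "GC": -2.36, "UA": -2.08,
           "GU": -1.40, "UG": -2.10},
    "GC": {"AU": -2.35, "CG": -3.42, "GC": -3.26, "UA": -2.24,
           "GU": -1.50, "UG": -2.50},
    "UA": {"AU": -1.33, "CG": -2.35, "GC": -2.11, "UA": -0.93,
           "GU": -1.00, "UG": -1.30},
    "GU": {"AU": -1.30, "CG": -2.50, "GC": -2.10, "UA": -1.40,
           "GU": -0.50, "UG": 0.00},
    "UG": {"AU": -1.00, "CG": -1.50, "GC": -1.40, "UA": -0.60,
           "GU": -0.30, "UG": -0.50},
}

# Loop initiation energies indexed by loop length (unpaired bases).
HAIRPIN_INIT = {3: 5.7, 4: 5.6, 5: 5.6, 6: 5.4, 7: 5.9, 8: 5.6, 9: 6.4}
BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
INTERNAL_INIT = {2: 1.5, 3: 1.8, 4: 1.7, 5: 1.8, 6: 2.0, 7: 2.2, 8: 2.3}

INTERNAL_ASYM = 0.5    # per unit of |l1 - l2|
INTERNAL_ASYM_MAX = 3.0

# Multiloop linear model: a + b per branch (closing pair included) +
# c per unpaired base inside the loop.
MULTI_A = 3.4
MULTI_B = 0.4
MULTI_C = 0.0

MIN_HAIRPIN = 3     # minimum unpaired bases in a hairpin loop
MAX_INTERIOR = 30   # max unpaired bases in a bulge/internal loop


def _extrapolate(table: dict[int, float], n: int) -> float:
    cap = max(table)
    if n <= cap:
        return table[n]
    return table[cap] + 1.75 * RT * math.log(n / cap)


def hairpin_energy(loop_len: int) -> float:
    """Initiation penalty of a hairpin loop of `loop_len` unpaired bases."""
    if loop_len < MIN_HAIRPIN:
        return math.inf
    return _extrapolate(HAIRPIN_INIT, loop_len)


def bulge_energy(loop_len: int) -> float:
    if loop_len < 1:
        return math.inf
    return _extrapolate(BULGE_INIT, loop_len)


def internal_energy(l1: int, l2: int) -> float:
    if l1 < 1 or l2 < 1:
        return math.inf
    init = _extrapolate(INTERNAL_INIT, l1 + l2)
    asym = min(INTERNAL_ASYM * abs(l1 - l2), INTERNAL_ASYM_MAX)
    return init + asym
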