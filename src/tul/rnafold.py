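"""Minimum-free-energy RNA secondary-structure prediction for short windows.

A nested-structure (pseudoknot-free) Zuker-style dynamic program over a
nearest-neighbour energy model: Watson-Crick and G·U wobble pairs, stacking
energies for adjacent pairs, size-dependent hairpin/bulge/internal-loop
penalties with Jacobson-Stockmayer extrapolation, and an affine multiloop
penalty.  The model is deliberately compact — no dangles, terminal
mismatches or special hairpins — so the predicted ΔG of any structure is an
exact sum of loop terms that an exhaustive enumerator can recompute, and so
the whole search space of a ≤40-nt window can be verified against brute
force.

Energies are handled internally as integer tenths of kcal/mol, which makes
equality between independent implementations exact rather than
floating-point-approximate.  The default table is a 30 °C-scaled variant of
the published 37 °C nearest-neighbour stack values (helix stacks are
enthalpy-dominated and strengthen at lower temperature; loop penalties,
being entropic, are left at their tabulated values).

Two-loops (stack/bulge/internal) are capped at MAXLOOP unpaired bases, the
standard restriction of folding implementations; structures containing a
larger two-loop are outside the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "FoldResult",
    "Hairpin",
    "fold_window",
    "mfe_fold",
    "eval_structure_tenths",
    "pairs_from_dotbracket",
    "extract_hairpin3",
    "MIN_HAIRPIN_LOOP",
    "MAXLOOP",
]

MIN_HAIRPIN_LOOP = 3
MAXLOOP = 10  # max total unpaired bases in a bulge/internal loop
INF = 10**9

_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}

# 37 °C nearest-neighbour stack free energies (kcal/mol); key "XY" is the
# 5'→3' pair X(i)-Y(j) stacked on the pair immediately interior to it.
_STACK37 = {
    ("AU", "AU"): -0.93, ("AU", "CG"): -2.24, ("AU", "GC"): -2.08,
    ("AU", "GU"): -0.55, ("AU", "UA"): -1.10, ("AU", "UG"): -1.36,
    ("CG", "AU"): -2.11, ("CG", "CG"): -3.26, ("CG", "GC"): -2.36,
    ("CG", "GU"): -1.41, ("CG", "UA"): -2.08, ("CG", "UG"): -2.11,
    ("GC", "AU"): -2.24, ("GC", "CG"): -3.42, ("GC", "GC"): -3.26,
    ("GC", "GU"): -2.51, ("GC", "UA"): -2.35, ("GC", "UG"): -1.53,
    ("GU", "AU"): -1.36, ("GU", "CG"): -2.11, ("GU", "GC"): -1.53,
    ("GU", "GU"): -0.50, ("GU", "UA"): -1.27, ("GU", "UG"): +1.29,
    ("UA", "AU"): -1.33, ("UA", "CG"): -2.35, ("UA", "GC"): -2.24,
    ("UA", "GU"): -1.27, ("UA", "UA"): -0.93, ("UA", "UG"): -1.00,
    ("UG", "AU"): -1.00, ("UG", "CG"): -2.51, ("UG", "GC"): -1.41,
    ("UG", "GU"): +0.30, ("UG", "UA"): -0.55, ("UG", "UG"): -0.50,
}

# tabulated loop initiation penalties (kcal/mol, 37 °C values kept as-is)
_HAIRPIN_BASE = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_BASE = {1: 3.9, 2: 3.1, 3: 3.5, 4: 4.2, 5: 4.8, 6: 5.0}
_INTERNAL_BASE = {2: 4.1, 3: 5.1, 4: 4.9, 5: 5.3, 6: 5.7}

# affine multiloop: a + b per interior branch (closing helix folded into a);
# unpaired multiloop bases are free
MULTI_A = 34  # tenths
MULTI_B = 4   # tenths

_RT_TENTHS = 0.001987 * 303.15 * 10  # kcal/mol→tenths at 30 °C
_TEMP_C = 30.0
# helix stacks strengthen below 37 °C; linear van't Hoff-style scaling
_STACK_SCALE = 1.0 + 0.013 * (37.0 - _TEMP_C)

_MAX_SIZE = 64


def _extrapolate(base: dict[int, float], n: int) -> float:
    m = max(base)
    if n <= m:
        return base[n]
    return base[m] + 1.75 * 0.001987 * 303.15 * math.log(n / m)


STACK = {k: round(v * _STACK_SCALE * 10) for k, v in _STACK37.items()}
HAIRPIN = {n: round(_extrapolate(_HAIRPIN_BASE, n) * 10) for n in range(3, _MAX_SIZE)}
BULGE = {n: round(_extrapolate(_BULGE_BASE, n) * 10) for n in range(1, _MAX_SIZE)}
INTERNAL = {n: round(_extrapolate(_INTERNAL_BASE, n) * 10) for n in range(2, _MAX_SIZE)}


def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return s


def can_pair(a: str, b: str) -> bool:
    return a + b in _PAIRS


def hairpin_energy_tenths(size: int) -> int:
    """Hairpin loop of `size` unpaired bases (size >= MIN_HAIRPIN_LOOP)."""
    return HAIRPIN[size]


def twoloop_energy_tenths(seq: str, i: int, j: int, k: int, l: int) -> int:
    """Energy of the two-loop between closing pair (i,j) and interior (k,l).

    Covers helix stacks (zero unpaired), bulges (one side unpaired) and
    internal loops.  Returns INF when the loop exceeds MAXLOOP.
    """
    n1, n2 = k - i - 1, j - l - 1
    if n1 < 0 or n2 < 0:
        raise ValueError("interior pair not inside closing pair")
    if n1 + n2 > MAXLOOP:
        return INF
    if n1 == 0 and n2 == 0:
        return STACK[(seq[i] + seq[j], seq[k] + seq[l])]
    if n1 == 0 or n2 == 0:
        return BULGE[n1 + n2]
    return INTERNAL[n1 + n2]


def multiloop_energy_tenths(n_branches: int) -> int:
    """Affine multiloop penalty for a loop with `n_branches` interior helices."""
    return MULTI_A + MULTI_B * n_branches


# ---------------------------------------------------------------------------
# structure evaluation (energy of a given pair set)


def pairs_from_dotbracket(structure: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return frozenset(pairs)


def _dotbracket(n: int, pairs) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def eval_structure_tenths(seq: str, pairs) -> int:
    """Total loop-sum energy (tenths of kcal/mol) of a nested pair set.

    This is the model's *definition* of a structure's energy: hairpin,
    two-loop and multiloop terms summed over the loop decomposition, with
    exterior bases free.  Returns INF for structures outside the model
    (two-loop span > MAXLOOP).
    """
    seq = _to_rna(seq)
    plist = sorted(pairs)
    for i, j in plist:
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"non-complementary pair ({i},{j})")
        if j - i - 1 < MIN_HAIRPIN_LOOP:
            raise ValueError(f"hairpin loop below minimum at pair ({i},{j})")
    # children of each pair (pairs immediately interior), exterior pairs under root
    total = 0
    children: dict[Optional[tuple[int, int]], list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in plist:  # sorted by i: parent is nearest enclosing pair
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    for p in plist:
        kids = children[p]
        i, j = p
        if not kids:
            total += hairpin_energy_tenths(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            e = twoloop_energy_tenths(seq, i, j, k, l)
            if e >= INF:
                return INF
            total += e
        else:
            total += multiloop_energy_tenths(len(kids))
    return total


# ---------------------------------------------------------------------------
# MFE dynamic program


def _mfe_tenths(seq: str) -> tuple[int, frozenset[tuple[int, int]]]:
    """Zuker-style DP returning (MFE in tenths, MFE pair set)."""
    n = len(seq)
    # V[i][j]: best energy of a structure closed by pair (i,j)
    V = [[INF] * n for _ in range(n)]
    # WM[i][j]: best energy of >=1 multiloop branches within [i,j]
    WM = [[INF] * n for _ in range(n)]

    def pairable(i: int, j: int) -> bool:
        return j - i - 1 >= MIN_HAIRPIN_LOOP and can_pair(seq[i], seq[j])

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable(i, j):
                best = hairpin_energy_tenths(j - i - 1)
                for k in range(i + 1, j):
                    if k - i - 1 > MAXLOOP:
                        break
                    for l in range(max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - (MAXLOOP - (k - i - 1))), j):
                        if V[k][l] < INF:
                            e = twoloop_energy_tenths(seq, i, j, k, l)
                            if e < INF and e + V[k][l] < best:
                                best = e + V[k][l]
                # multiloop closed by (i,j): >=2 interior branches
                for k in range(i + 1, j):
                    if WM[i + 1][k - 1] < INF and WM[k][j - 1] < INF:
                        cand = MULTI_A + WM[i + 1][k - 1] + WM[k][j - 1]
                        if cand < best:
                            best = cand
                V[i][j] = best
            # WM
            best_wm = INF
            if WM[i + 1][j] < best_wm:
                best_wm = WM[i + 1][j]
            if WM[i][j - 1] < best_wm:
                best_wm = WM[i][j - 1]
            if V[i][j] < INF and V[i][j] + MULTI_B < best_wm:
                best_wm = V[i][j] + MULTI_B
            for k in range(i + 1, j + 1):
                if WM[i][k - 1] < INF and WM[k][j] < INF:
                    cand = WM[i][k - 1] + WM[k][j]
                    if cand < best_wm:
                        best_wm = cand
            WM[i][j] = best_wm

    # exterior loop
    W = [0] * (n + 1)  # W[j+1] = best energy over prefix [0..j]
    choice: list[Optional[tuple[int, int]]] = [None] * (n + 1)
    for j in range(n):
        best = W[j]
        pick = None
        for i in range(0, j):
            if V[i][j] < INF and W[i] + V[i][j] < best:
                best = W[i] + V[i][j]
                pick = (i, j)
        W[j + 1] = best
        choice[j + 1] = pick

    # traceback
    pairs: set[tuple[int, int]] = []  # type: ignore[assignment]
    pairs = set()

    def trace_v(i: int, j: int) -> None:
        pairs.add((i, j))
        e = V[i][j]
        if e == hairpin_energy_tenths(j - i - 1):
            # prefer hairpin when degenerate
            return
        for k in range(i + 1, j):
            if k - i - 1 > MAXLOOP:
                break
            for l in range(max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - (MAXLOOP - (k - i - 1))), j):
                if V[k][l] < INF:
                    te = twoloop_energy_tenths(seq, i, j, k, l)
                    if te < INF and te + V[k][l] == e:
                        trace_v(k, l)
                        return
        for k in range(i + 1, j):
            if WM[i + 1][k - 1] < INF and WM[k][j - 1] < INF:
                if MULTI_A + WM[i + 1][k - 1] + WM[k][j - 1] == e:
                    trace_wm(i + 1, k - 1)
                    trace_wm(k, j - 1)
                    return
        raise AssertionError("traceback failed in V")

    def trace_wm(i: int, j: int) -> None:
        e = WM[i][j]
        if e >= INF:
            raise AssertionError("traceback into infeasible WM")
        if WM[i + 1][j] == e:
            trace_wm(i + 1, j)
            return
        if WM[i][j - 1] == e:
            trace_wm(i, j - 1)
            return
        if V[i][j] < INF and V[i][j] + MULTI_B == e:
            trace_v(i, j)
            return
        for k in range(i + 1, j + 1):
            if WM[i][k - 1] < INF and WM[k][j] < INF and WM[i][k - 1] + WM[k][j] == e:
                trace_wm(i, k - 1)
                trace_wm(k, j)
                return
        raise AssertionError("traceback failed in WM")

    j = n
    while j > 0:
        if choice[j] is None:
            j -= 1
        else:
            i, jj = choice[j]
            trace_v(i, jj)
            j = i

    return W[n], frozenset(pairs)


@dataclass(frozen=True)
class Hairpin:
    """The 3'-most hairpin of a structure: its closing helix and loop."""

    stem_length: int
    loop_length: int
    stem_close_pos: int  # index of the 3'-most paired base of the closing helix


@dataclass(frozen=True)
class FoldResult:
    delta_g: float  # kcal/mol, <= 0
    structure: str  # dot-bracket, same length as input
    hairpin3: Optional[Hairpin]
    truncated: bool = False  # input shorter than the nominal window

    @property
    def is_folded(self) -> bool:
        return self.hairpin3 is not None


def extract_hairpin3(structure: str) -> Optional[Hairpin]:
    """The 3'-most hairpin and the continuous helix closing its loop."""
    pairs = pairs_from_dotbracket(structure)
    if not pairs:
        return None
    pairset = set(pairs)
    inner = [
        (i, j)
        for (i, j) in pairs
        if not any(i < a and b < j for (a, b) in pairs)
    ]
    i, j = max(inner)  # 3'-most hairpin
    stem = 1
    while (i - stem, j + stem) in pairset:
        stem += 1
    return Hairpin(stem_length=stem, loop_length=j - i - 1, stem_close_pos=j + stem - 1)


def mfe_fold(seq: str) -> tuple[float, str]:
    """MFE (kcal/mol) and dot-bracket structure of an RNA/DNA string."""
    s = _to_rna(seq)
    if len(s) < MIN_HAIRPIN_LOOP + 2:
        return 0.0, "." * len(s)
    tenths, pairs = _mfe_tenths(s)
    if tenths >= 0:
        return 0.0, "." * len(s)
    return tenths / 10.0, _dotbracket(len(s), pairs)


def fold_window(seq: str, temperature: float = 30.0, expected_length: int = 40) -> FoldResult:
    """Fold one upstream window (nominally 40 nt) ending at a 3'-end site.

    Shorter inputs (site near a contig edge) are folded as-is and flagged
    ``truncated``.  Only the 30 °C energy table is bundled; other
    temperatures are rejected rather than silently approximated.
    """
    if temperature != _TEMP_C:
        raise NotImplementedError(
            f"only the {_TEMP_C:g} degC energy table is bundled"
        )
    dg, structure = mfe_fold(seq)
    return FoldResult(
        delta_g=dg,
        structure=structure,
        hairpin3=extract_hairpin3(structure),
        truncated=len(seq) < expected_length,
    )
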