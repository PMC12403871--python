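"""Independent oracles used by the test suite.

Two routes to the MFE that do not share code with the production DP:

* :func:`enumerate_structures` / :func:`mfe_by_full_enumeration` — literally
  every non-crossing set of complementary pairs (min hairpin loop 3),
  scored one by one with the model's loop-sum energy definition.  Only
  feasible for short sequences; it anchors everything else.
* :func:`mfe_by_loop_search` — exhaustive top-down search over loop
  decompositions (hairpin / two-loop / explicit multiloop branch
  placements) with memoized interval minima.  No Zuker V/WM/affine
  machinery; multiloop branches are enumerated explicitly.  Agrees with the
  full enumeration wherever the latter is feasible and scales to 40 nt.

Both score structures through ``eval_structure_tenths`` /
``twoloop_energy_tenths`` etc., i.e. the same energy table the production
folder uses — the point of the check is the search, not the table.

Also here: a brute-force single-linkage clustering oracle for site merging
and a brute-force median-of-ratios recomputation.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from tul.rnafold import (
    INF,
    MIN_HAIRPIN_LOOP,
    can_pair,
    eval_structure_tenths,
    hairpin_energy_tenths,
    multiloop_energy_tenths,
    twoloop_energy_tenths,
    _to_rna,
)


def candidate_pairs(seq: str) -> list[tuple[int, int]]:
    seq = _to_rna(seq)
    n = len(seq)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n)
        if can_pair(seq[i], seq[j])
    ]


def enumerate_structures(seq: str, limit: int = 2_000_000):
    """Yield every non-crossing subset of candidate pairs (incl. empty)."""
    pairs = candidate_pairs(seq)
    count = 0

    def compatible(p, q):
        (i, j), (k, l) = p, q
        if len({i, j, k, l}) < 4:
            return False
        # non-crossing: nested or disjoint
        return (k > j) or (i > l) or (i < k and l < j) or (k < i and j < l)

    def rec(chosen: tuple, remaining: list):
        nonlocal count
        count += 1
        if count > limit:
            raise RuntimeError("structure space too large for full enumeration")
        yield chosen
        for idx, p in enumerate(remaining):
            if all(compatible(p, q) for q in chosen):
                yield from rec(chosen + (p,), remaining[idx + 1 :])

    yield from rec(tuple(), pairs)


def mfe_by_full_enumeration(seq: str, limit: int = 2_000_000) -> float:
    """MFE (kcal/mol) by scoring every structure; empty structure = 0."""
    best = 0
    for structure in enumerate_structures(seq, limit=limit):
        e = eval_structure_tenths(seq, frozenset(structure))
        if e < best:
            best = e
    return best / 10.0


def mfe_by_loop_search(seq: str) -> float:
    """MFE by exhaustive loop-decomposition search (memoized, no affine DP)."""
    s = _to_rna(seq)
    n = len(s)

    @lru_cache(maxsize=None)
    def closed(i: int, j: int) -> int:
        """Best energy of any structure closed by the pair (i, j)."""
        if j - i - 1 < MIN_HAIRPIN_LOOP or not can_pair(s[i], s[j]):
            return INF
        best = hairpin_energy_tenths(j - i - 1)
        # two-loop: exactly one interior branch
        for k in range(i + 1, j):
            for l in range(k + MIN_HAIRPIN_LOOP + 1, j):
                inner = closed(k, l)
                if inner >= INF:
                    continue
                e = twoloop_energy_tenths(s, i, j, k, l)
                if e < INF and e + inner < best:
                    best = e + inner
        # multiloop: enumerate every placement of >= 2 interior branches
        for branches, energy in branch_sets(i + 1, j - 1, 2):
            cand = multiloop_energy_tenths(branches) + energy
            if cand < best:
                best = cand
        return best

    @lru_cache(maxsize=None)
    def _branch_options(a: int, b: int) -> tuple:
        """All (n_branches, total_energy) of >= 1 branch placements in [a, b],
        where the first branch starts exactly at position a."""
        options = []
        for l in range(a + MIN_HAIRPIN_LOOP + 1, b + 1):
            e0 = closed(a, l)
            if e0 >= INF:
                continue
            options.append((1, e0))
            for a2 in range(l + 1, b - MIN_HAIRPIN_LOOP):
                for nb, e in _branch_options(a2, b):
                    options.append((1 + nb, e0 + e))
        # keep the minimum per branch count (sufficient for minimization)
        best: dict[int, int] = {}
        for nb, e in options:
            if nb not in best or e < best[nb]:
                best[nb] = e
        return tuple(sorted(best.items()))

    def branch_sets(a: int, b: int, min_branches: int):
        for a0 in range(a, b - MIN_HAIRPIN_LOOP):
            for nb, e in _branch_options(a0, b):
                if nb >= min_branches:
                    yield nb, e

    best = 0

    @lru_cache(maxsize=None)
    def exterior(j: int) -> int:
        """Best energy over the prefix s[0..j]."""
        if j < 0:
            return 0
        e = exterior(j - 1)  # j unpaired
        for i in range(0, j - MIN_HAIRPIN_LOOP):
            c = closed(i, j)
            if c < INF:
                cand = exterior(i - 1) + c
                if cand < e:
                    e = cand
        return e

    best = exterior(n - 1)
    return min(best, 0) / 10.0


# ---------------------------------------------------------------------------
# other brute-force oracles


def single_linkage_clusters(positions: list[int], window: int) -> list[list[int]]:
    """Brute-force single-linkage clustering of 1-D positions at <= window."""
    clusters = [[p] for p in sorted(positions)]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(clusters)), 2):
            if any(
                abs(p - q) <= window for p in clusters[a] for q in clusters[b]
            ):
                clusters[a] = clusters[a] + clusters[b]
                del clusters[b]
                changed = True
                break
    return [sorted(c) for c in clusters]


def median_of_ratios(matrix: np.ndarray) -> np.ndarray:
    """Direct median-of-ratios on sorted ratio lists (no log trick)."""
    rows_ok = (matrix > 0).all(axis=1)
    sub = matrix[rows_ok].astype(float)
    geo = np.prod(sub, axis=1) ** (1.0 / sub.shape[1])
    factors = []
    for j in range(matrix.shape[1]):
        ratios = sorted(sub[:, j] / geo)
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2])
        factors.append(med)
    return np.array(factors)
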