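"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from scratch against the problem
definitions (canonical pairs, nesting, minimum hairpin of three unpaired
bases, pair+stack energies) without reusing the package's DP, neighbor or
flooding code paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

CANON = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

PAIR_E = {"GC": -3.0, "CG": -3.0, "AU": -2.0, "UA": -2.0, "GU": -1.0, "UG": -1.0}
STACK_E = -1.0


def can_pair(seq: str, i: int, j: int) -> bool:
    """1-based canonical pair with at least 3 unpaired bases enclosed."""
    return j - i >= 4 and (seq[i - 1], seq[j - 1]) in CANON


def all_structures(seq: str):
    """Every pseudoknot-free pair set, by interval recursion on position 1."""
    n = len(seq)

    def rec(i, j):
        if j - i < 4:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + 4, j + 1):
            if can_pair(seq, i, k):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield inner | {(i, k)} | outer

    yield from rec(1, n)


def count_structures(seq: str) -> int:
    """Memoized count of valid structures (independent of the generator)."""
    n = len(seq)
    memo: dict[tuple[int, int], int] = {}

    def rec(i, j):
        if j - i < 4:
            return 1
        if (i, j) in memo:
            return memo[(i, j)]
        total = rec(i + 1, j)
        for k in range(i + 4, j + 1):
            if can_pair(seq, i, k):
                total += rec(i + 1, k - 1) * rec(k + 1, j)
        memo[(i, j)] = total
        return total

    return rec(1, n)


def energy(seq: str, pairs: frozenset, potential: dict | None = None) -> float:
    """Pair+stack energy in kcal/mol, plus optional pair pseudo-energies."""
    e = 0.0
    for i, j in pairs:
        e += PAIR_E[seq[i - 1] + seq[j - 1]]
        if (i + 1, j - 1) in pairs:
            e += STACK_E
    if potential:
        e += sum(potential.get(p, 0.0) for p in pairs)
    return e


def partition_sum(seq: str, beta: float, potential: dict | None = None) -> float:
    return sum(math.exp(-beta * energy(seq, s, potential)) for s in all_structures(seq))


def dotbracket(pairs: frozenset, n: int) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def crossing(p, q) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def neighbors(seq: str, pairs: frozenset):
    """Single base-pair additions/removals, by direct scan."""
    n = len(seq)
    out = set()
    for p in pairs:
        out.add(pairs - {p})
    occupied = {x for p in pairs for x in p}
    for i in range(1, n + 1):
        for j in range(i + 4, n + 1):
            if i in occupied or j in occupied or not can_pair(seq, i, j):
                continue
            if any(crossing((i, j), p) for p in pairs):
                continue
            out.add(pairs | {(i, j)})
    return out


def steepest_descent(seq: str, pairs: frozenset, potential: dict | None = None):
    """Gradient walk: strictly lowest-energy neighbor, dot-bracket tie-break."""
    n = len(seq)
    cur = pairs
    while True:
        cur_e = energy(seq, cur, potential)
        best = None
        best_key = None
        for nb in neighbors(seq, cur):
            e = energy(seq, nb, potential)
            if e < cur_e - 1e-12:
                key = (e, dotbracket(nb, n))
                if best_key is None or key < best_key:
                    best, best_key = nb, key
        if best is None:
            return cur
        cur = best


def connection_energy(seq: str, structures, a: frozenset, b: frozenset) -> float:
    """Minimax (bottleneck) saddle energy between two structures.

    Union-find sweep over all structures sorted by (energy, dot-bracket):
    the energy of the structure whose insertion first connects a and b.
    """
    n = len(seq)
    order = sorted(structures, key=lambda s: (energy(seq, s), dotbracket(s, n)))
    parent: dict[frozenset, frozenset] = {}

    def find(x):
        while parent[x] is not x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    present = set()
    for s in order:
        parent[s] = s
        present.add(s)
        for nb in neighbors(seq, s):
            if nb in present:
                ra, rb = find(s), find(nb)
                if ra is not rb:
                    parent[rb] = ra
        if a in present and b in present and find(a) is find(b):
            return energy(seq, s)
    raise AssertionError("structures never connected")
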