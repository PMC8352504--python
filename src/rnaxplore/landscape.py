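"""Energy-landscape coarse graining: moves, gradient basins, barrier trees.

The move set connects structures differing by exactly one base pair.  A
gradient walk repeatedly steps to the strictly lowest-energy neighbor
(lexicographically smallest dot-bracket on ties) and ends in a local
minimum; the walk endpoints partition the conformation space into gradient
basins.  Exhaustive flooding of an enumerated landscape yields the barrier
tree: leaves are local minima, internal nodes the lowest saddles connecting
their basins.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

from .energy import EnergyModel, PairPotential
from .structures import RnaSequence, SecondaryStructure
from .thermo import SampleSet

__all__ = [
    "neighbors",
    "gradient_walk",
    "BasinMap",
    "build_basin_map",
    "BarrierTree",
    "Merge",
    "build_barrier_tree",
    "barrier_coverage",
]


def neighbors(seq: RnaSequence, s: SecondaryStructure) -> set[SecondaryStructure]:
    """All structures reachable by removing or adding one base pair.

    The relation is symmetric: t in N(s) iff s in N(t).
    """
    n = seq.n
    out: set[SecondaryStructure] = set()
    for p in s.pairs:
        out.add(SecondaryStructure(s.pairs - {p}, n))
    paired = s.pair_of
    plist = sorted(s.pairs)
    free = [i for i in range(1, n + 1) if i not in paired]
    for ai, i in enumerate(free):
        for j in free[ai + 1:]:
            if not seq.can_pair(i, j):
                continue
            ok = True
            for k, l in plist:
                if k < i < l < j or i < k < j < l:
                    ok = False
                    break
            if ok:
                out.add(SecondaryStructure(s.pairs | {(i, j)}, n))
    return out


def _energy_c(
    model: EnergyModel,
    seq: RnaSequence,
    s: SecondaryStructure,
    potential: PairPotential | None,
) -> int | Fraction:
    e = model.structure_energy_c(seq, s)
    if potential is not None:
        g = potential.guiding_term_exact(s)
        if g != 0:
            return e + g * 100
    return e


def gradient_walk(
    seq: RnaSequence,
    model: EnergyModel,
    s: SecondaryStructure,
    potential: PairPotential | None = None,
    cache: dict[SecondaryStructure, SecondaryStructure] | None = None,
) -> SecondaryStructure:
    """Steepest-descent walk to the local minimum of s's gradient basin.

    Moves to the neighbor of strictly lowest energy, breaking energy ties by
    lexicographically smallest dot-bracket; stops at a structure with no
    strictly lower neighbor (plateaus therefore count as minima).  ``cache``
    memoises endpoints for every structure on the trajectory.
    """
    path: list[SecondaryStructure] = []
    cur = s
    cur_e = None
    while True:
        if cache is not None and cur in cache:
            cur = cache[cur]
            break
        path.append(cur)
        if cur_e is None:
            cur_e = _energy_c(model, seq, cur, potential)
        best = None
        best_key = None
        for nb in neighbors(seq, cur):
            e = _energy_c(model, seq, nb, potential)
            if e < cur_e:
                key = (e, nb.dotbracket)
                if best_key is None or key < best_key:
                    best, best_key = nb, key
        if best is None:
            break
        cur, cur_e = best, best_key[0]
    if cache is not None:
        for t in path:
            cache[t] = cur
    return cur


@dataclass
class BasinMap:
    """Observed structures mapped to their gradient-walk local minima.

    ``counts`` accumulates sample multiplicities per minimum; ``round_counts``
    keeps the per-round increments; M1/M>1 split minima seen once vs several
    times (cumulatively).
    """

    assignments: dict[SecondaryStructure, SecondaryStructure] = field(default_factory=dict)
    counts: Counter = field(default_factory=Counter)
    round_counts: dict[int, Counter] = field(default_factory=dict)

    def add(self, sample: SecondaryStructure, minimum: SecondaryStructure,
            round_index: int = 0, multiplicity: int = 1) -> None:
        self.assignments[sample] = minimum
        self.counts[minimum] += multiplicity
        self.round_counts.setdefault(round_index, Counter())[minimum] += multiplicity

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def singletons(self) -> set[SecondaryStructure]:
        """M1: minima attracting exactly one sample so far."""
        return {m for m, c in self.counts.items() if c == 1}

    def multiples(self) -> set[SecondaryStructure]:
        """M>1: minima attracting more than one sample so far."""
        return {m for m, c in self.counts.items() if c > 1}


def build_basin_map(
    seq: RnaSequence,
    model: EnergyModel,
    samples: SampleSet,
    potential: PairPotential | None = None,
    cache: dict[SecondaryStructure, SecondaryStructure] | None = None,
    round_index: int = 0,
    into: BasinMap | None = None,
) -> BasinMap:
    """Gradient-walk every sampled structure to its minimum and count basins.

    Walks use the unmodified energy unless a potential is explicitly given:
    local minima are features of the true landscape, the potential only
    shapes sampling.
    """
    bm = into if into is not None else BasinMap()
    if cache is None:
        cache = {}
    for s, mult in samples.counts().items():
        m = gradient_walk(seq, model, s, potential, cache)
        bm.add(s, m, round_index, mult)
    return bm


# ---------------------------------------------------------------------------
# Barrier trees by exhaustive flooding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Merge:
    """A saddle joining two basins; deepest minimum on each side recorded."""

    deeper_min: SecondaryStructure
    shallower_min: SecondaryStructure
    saddle: SecondaryStructure
    saddle_energy: float


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def add(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, root_keep: int, root_absorb: int) -> None:
        self.parent[root_absorb] = root_keep


@dataclass
class BarrierTree:
    """Barrier tree of an exhaustively enumerated landscape.

    ``leaves`` are the coarse-grained local minima (barrier >= the merge
    threshold), ``merges`` the recorded saddles in increasing saddle order,
    ``mapping`` sends every enumerated structure to the index of its leaf.
    """

    leaves: list[tuple[SecondaryStructure, float]]
    merges: list[Merge]
    mapping: dict[SecondaryStructure, int]
    merge_threshold: float
    complete: bool = True

    @property
    def leaf_structures(self) -> set[SecondaryStructure]:
        return {s for s, _ in self.leaves}

    def barrier_between(
        self, a: SecondaryStructure, b: SecondaryStructure
    ) -> float:
        """Saddle energy of the merge that first connects the leaves a and b."""
        ids = {s: i for i, (s, _) in enumerate(self.leaves)}
        uf = _UnionFind()
        for i in range(len(self.leaves)):
            uf.add(i)
        ia, ib = ids[a], ids[b]
        for mg in self.merges:
            ra, rb = uf.find(ids[mg.deeper_min]), uf.find(ids[mg.shallower_min])
            if ra != rb:
                uf.union(ra, rb)
            if uf.find(ia) == uf.find(ib):
                return mg.saddle_energy
        raise ValueError("leaves are not connected in this tree")


def build_barrier_tree(
    enumeration: list[tuple[SecondaryStructure, float]],
    seq: RnaSequence,
    model: EnergyModel,
    merge_threshold: float = 3.0,
) -> BarrierTree:
    """Flood an enumerated landscape into a barrier tree.

    Structures are processed in increasing (energy, dot-bracket) order.  A
    structure with no processed neighbor opens a new basin (a local
    minimum); with processed neighbors in one basin it joins that basin;
    with neighbors in several basins it is a saddle merging them at its
    energy.  Afterwards, minima whose barrier (saddle minus own energy) is
    below ``merge_threshold`` are absorbed into the deeper neighbor basin.
    Basins adjacent to structures missing from the enumeration (finite
    energy band) are flagged with a warning and ``complete=False``.
    """
    items = [(model.structure_energy_c(seq, s), s) for s, _ in enumeration]
    items.sort(key=lambda t: (t[0], t[1].dotbracket))
    known = {s for _, s in items}
    thr_c = merge_threshold * 100

    assign: dict[SecondaryStructure, int] = {}
    basin_min: dict[int, tuple[int, SecondaryStructure]] = {}
    uf = _UnionFind()          # full flooding components
    absorb_uf = _UnionFind()   # absorptions only: leaf identity
    events: list[tuple[int, SecondaryStructure, list[int]]] = []
    boundary = False
    next_id = 0

    def deeper(a: int, b: int) -> tuple[int, int]:
        ka = (basin_min[a][0], basin_min[a][1].dotbracket)
        kb = (basin_min[b][0], basin_min[b][1].dotbracket)
        return (a, b) if ka <= kb else (b, a)

    merges: list[Merge] = []
    absorbed: set[int] = set()
    all_leaves: list[tuple[int, SecondaryStructure, int]] = []  # (id, s, e_c)

    for e_c, s in items:
        nbrs = neighbors(seq, s)
        roots = []
        for nb in nbrs:
            if nb in assign:
                r = uf.find(assign[nb])
                if r not in roots:
                    roots.append(r)
            elif nb not in known:
                boundary = True
        if not roots:
            bid = next_id
            next_id += 1
            uf.add(bid)
            absorb_uf.add(bid)
            basin_min[bid] = (e_c, s)
            all_leaves.append((bid, s, e_c))
            assign[s] = bid
        elif len(roots) == 1:
            assign[s] = roots[0]
        else:
            # saddle: merge all adjacent basins at this energy, deepest first
            roots.sort(key=lambda r: (basin_min[r][0], basin_min[r][1].dotbracket))
            keep = roots[0]
            for other in roots[1:]:
                dp, sh = deeper(keep, other)
                dmin, smin = basin_min[dp][1], basin_min[sh][1]
                barrier_c = e_c - basin_min[sh][0]
                if barrier_c < thr_c:
                    absorbed.add(sh)
                    absorb_uf.union(absorb_uf.find(dp), absorb_uf.find(sh))
                else:
                    merges.append(Merge(dmin, smin, s, e_c / 100.0))
                uf.union(dp, sh)
                keep = dp
            assign[s] = keep

    leaves = [(s, e_c / 100.0) for bid, s, e_c in all_leaves if bid not in absorbed]
    leaf_index = {bid: idx for idx, (bid, s, e_c) in enumerate(
        (t for t in all_leaves if t[0] not in absorbed)
    )}
    # leaf identity follows absorptions only
    root_to_leaf = {}
    for bid, s, e_c in all_leaves:
        if bid not in absorbed:
            root_to_leaf[bid] = leaf_index[bid]
    mapping: dict[SecondaryStructure, int] = {}
    for s, bid in assign.items():
        r = absorb_uf.find(bid)
        mapping[s] = root_to_leaf[r]

    if boundary:
        warnings.warn(
            "enumeration appears band-limited: some neighbors fall outside "
            "the enumerated set; saddles above the band are missing",
            stacklevel=2,
        )
    return BarrierTree(leaves, merges, mapping, merge_threshold, complete=not boundary)


def barrier_coverage(
    tree: BarrierTree,
    basins_found: set[SecondaryStructure],
    top_k: int = 100,
) -> tuple[float, float]:
    """(barrier_fraction, basin_fraction) of a set of discovered minima.

    Merges are ranked by saddle height descending; a merge is covered when
    the deepest minimum on each of its two sides was found.  The basin
    fraction is the share of tree leaves among the found minima.  With no
    merges the barrier fraction is vacuously 1.
    """
    leaves = tree.leaf_structures
    basin_fraction = len(basins_found & leaves) / len(leaves) if leaves else 0.0
    ranked = sorted(
        tree.merges, key=lambda m: (-m.saddle_energy, m.saddle.dotbracket)
    )[:top_k]
    if not ranked:
        return 1.0, basin_fraction
    covered = sum(
        1 for m in ranked
        if m.deeper_min in basins_found and m.shallower_min in basins_found
    )
    return covered / len(ranked), basin_fraction
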