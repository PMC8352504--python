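import math
import warnings
from collections import Counter

import pytest

from rnaxplore import (
    RnaSequence,
    SecondaryStructure,
    barrier_coverage,
    build_barrier_tree,
    build_basin_map,
    enumerate_structures,
    gradient_walk,
    neighbors,
    parse_dotbracket,
)
from rnaxplore.thermo import SampleSet

from _oracles import (
    all_structures,
    connection_energy,
    neighbors as oracle_neighbors,
    steepest_descent,
)


def test_neighbors_match_brute_force_scan(model):
    seq = RnaSequence("GGCAUAAAGUGCC")
    for pairs in all_structures(seq.residues):
        s = SecondaryStructure(frozenset(pairs), seq.n)
        got = {frozenset(t.pairs) for t in neighbors(seq, s)}
        assert got == {frozenset(p) for p in oracle_neighbors(seq.residues, frozenset(pairs))}


def test_neighbors_symmetric_and_removals_always_present():
    seq = RnaSequence("GGGAAACCC")
    s = parse_dotbracket("(((...)))")
    nb = neighbors(seq, s)
    for p in s.pairs:
        assert SecondaryStructure(s.pairs - {p}, seq.n) in nb
    for t in nb:
        assert s in neighbors(seq, t)


def test_open_chain_neighbors():
    assert neighbors(RnaSequence("AAAAA"), parse_dotbracket(".....")) == set()
    seq = RnaSequence("GGGAAACCC")
    nb = neighbors(seq, parse_dotbracket("........."))
    assert all(len(t.pairs) == 1 for t in nb)
    assert {next(iter(t.pairs)) for t in nb} == {
        (i, j)
        for i in range(1, 10)
        for j in range(i + 4, 10)
        if seq.can_pair(i, j)
    }


def test_gradient_walk_idempotent_on_minimum(model, triple_helix):
    mfe = parse_dotbracket("(((...)))")
    assert gradient_walk(triple_helix, model, mfe) == mfe


def test_gradient_walk_from_open_chain_matches_oracle(model, triple_helix):
    # the lexicographic tie-break steers the first step to pair (1,7),
    # a dead end: the walk ends there, exactly as brute-force descent does
    end = gradient_walk(triple_helix, model, parse_dotbracket("........."))
    want = steepest_descent(triple_helix.residues, frozenset())
    assert frozenset(end.pairs) == frozenset(want) == frozenset({(1, 7)})


@pytest.mark.parametrize("residues", ["GGCAUAAAGUGCC", "GCCGAAAACGGCAC"])
def test_gradient_walk_agrees_with_oracle_everywhere(model, residues):
    seq = RnaSequence(residues)
    cache = {}
    for pairs in all_structures(residues):
        s = SecondaryStructure(frozenset(pairs), seq.n)
        ours = gradient_walk(seq, model, s, cache=cache)
        theirs = steepest_descent(residues, frozenset(pairs))
        assert frozenset(ours.pairs) == frozenset(theirs)


def test_basins_partition_the_conformation_space(model):
    seq = RnaSequence("GGCAUAAAGUGCC")
    enum = enumerate_structures(seq, model)
    ss = SampleSet(tuple(s for s, _ in enum), None, "exhaustive")
    bm = build_basin_map(seq, model, ss)
    assert bm.total == len(enum)
    assert set(bm.assignments) == {s for s, _ in enum}
    for minimum in bm.counts:
        assert gradient_walk(seq, model, minimum) == minimum
    assert sum(bm.counts.values()) == len(enum)


def test_basin_map_trivial_cases(model, triple_helix):
    mfe = parse_dotbracket("(((...)))")
    ss = SampleSet((mfe,) * 5, None, "x")
    bm = build_basin_map(triple_helix, model, ss)
    assert bm.counts == Counter({mfe: 5})
    empty = build_basin_map(triple_helix, model, SampleSet((), None, "x"))
    assert not empty.counts and not empty.assignments


def _full_tree(seq, model, threshold=0.0):
    enum = enumerate_structures(seq, model)
    return build_barrier_tree(enum, seq, model, merge_threshold=threshold), enum


def test_single_minimum_landscape(model):
    seq = RnaSequence("GGGGAAAACCCC")  # funnel to one helix
    tree, _ = _full_tree(seq, model, threshold=math.inf)
    assert len(tree.leaves) == 1
    assert tree.merges == []
    assert barrier_coverage(tree, tree.leaf_structures) == (1.0, 1.0)


def test_merge_threshold_infinite_leaves_single_basin(model, bistable, bistable_enum):
    tree = build_barrier_tree(bistable_enum, bistable, model, merge_threshold=math.inf)
    assert len(tree.leaves) == 1


def test_merge_threshold_monotonicity(model, bistable, bistable_enum):
    counts = []
    for thr in (0.0, 1.0, 2.0, 3.0, 5.0, math.inf):
        tree = build_barrier_tree(bistable_enum, bistable, model, merge_threshold=thr)
        counts.append(len(tree.leaves))
    assert counts == sorted(counts, reverse=True)


def test_tree_invariants(model, bistable, bistable_enum):
    tree = build_barrier_tree(bistable_enum, bistable, model, merge_threshold=0.0)
    energies = dict(tree.leaves)
    assert len(tree.merges) == len(tree.leaves) - 1
    for mg in tree.merges:
        assert mg.saddle_energy >= energies[mg.deeper_min] - 1e-9
        assert mg.saddle_energy >= energies[mg.shallower_min] - 1e-9
        assert energies[mg.deeper_min] <= energies[mg.shallower_min]
    assert set(tree.mapping.values()) <= set(range(len(tree.leaves)))


@pytest.mark.parametrize("residues", ["GGCAUAAAGUGCC", "GCACAAAGUGCAAAGC"])
def test_barriers_equal_minimax_path_oracle(model, residues):
    seq = RnaSequence(residues)
    tree, enum = _full_tree(seq, model, threshold=0.0)
    structs = [frozenset(s.pairs) for s, _ in enum]
    leaves = [s for s, _ in tree.leaves]
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            got = tree.barrier_between(leaves[a], leaves[b])
            want = connection_energy(
                residues, structs, frozenset(leaves[a].pairs), frozenset(leaves[b].pairs)
            )
            assert got == pytest.approx(want, abs=1e-9)


def test_band_limited_enumeration_warns(model, bistable):
    enum = enumerate_structures(bistable, model, band=4.0)
    with pytest.warns(UserWarning, match="band-limited"):
        tree = build_barrier_tree(enum, bistable, model)
    assert not tree.complete


def test_barrier_coverage_extremes(model, bistable, bistable_enum):
    tree = build_barrier_tree(bistable_enum, bistable, model, merge_threshold=0.0)
    assert barrier_coverage(tree, set()) == (0.0, 0.0)
    full = barrier_coverage(tree, tree.leaf_structures)
    assert full == (1.0, 1.0)
    # only the global minimum: no merge has both sides, one leaf covered
    deepest = min(tree.leaves, key=lambda t: t[1])[0]
    bf, sf = barrier_coverage(tree, {deepest})
    assert bf == 0.0
    assert sf == pytest.approx(1 / len(tree.leaves))


def test_barrier_coverage_top_k_ranking(model, bistable, bistable_enum):
    tree = build_barrier_tree(bistable_enum, bistable, model, merge_threshold=0.0)
    ranked = sorted(tree.merges, key=lambda m: (-m.saddle_energy, m.saddle.dotbracket))
    top = ranked[0]
    bf, _ = barrier_coverage(tree, {top.deeper_min, top.shallower_min}, top_k=1)
    assert bf == 1.0
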