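import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaxplore import (
    PairPotential,
    RnaSequence,
    SecondaryStructure,
    XplorerConfig,
    accumulate_potential,
    boltzmann_sample,
    gradient_walk,
    parse_dotbracket,
    partition_function,
    repellent_penalty,
    run_xplorer,
    saturation_ratio,
    select_repellent_target,
)
from rnaxplore.landscape import BasinMap
from rnaxplore.xplorer import repellent_penalty_exact

from _oracles import all_structures


def test_repellent_penalty_full_overlap_gives_alpha():
    ref = parse_dotbracket("(((...)))")
    assert repellent_penalty(ref, ref, 0.61) == pytest.approx(0.61)


def test_repellent_penalty_disjoint_gives_zero():
    ref = parse_dotbracket("(((...))).....")
    s = parse_dotbracket(".........(...)" .replace(" ", ""))
    assert repellent_penalty(ref, s, 0.61) == 0.0


def test_repellent_penalty_partial_overlap():
    ref = SecondaryStructure.from_pairs([(1, 12), (2, 11), (3, 10), (4, 9)], 12)
    s = SecondaryStructure.from_pairs([(1, 12), (2, 11)], 12)
    assert repellent_penalty(ref, s, 0.6) == pytest.approx(0.3)


def test_repellent_penalty_rejects_open_chain_reference():
    with pytest.raises(ValueError):
        repellent_penalty(parse_dotbracket("....."), parse_dotbracket("....."), 0.5)


def test_accumulate_appends_history_and_zero_alpha_is_noop():
    ref = parse_dotbracket("(((...)))")
    pot = accumulate_potential(PairPotential.zero(), ref, 0.0)
    assert pot.is_zero() and len(pot.history) == 1
    pot2 = accumulate_potential(pot, ref, 0.5)
    assert float(pot2.guiding_term_exact(ref)) == pytest.approx(0.5)


def test_closed_form_identity_over_random_updates():
    # per-pair accumulated pseudo-energy equals the sum of per-reference
    # penalties, exactly, for arbitrary structures
    seq = "GGCAUAAAGUGCC"
    structs = [SecondaryStructure(frozenset(p), len(seq)) for p in all_structures(seq)]
    structs = [s for s in structs if s.pairs]
    rng = np.random.default_rng(11)
    pot = PairPotential.zero()
    refs = []
    for _ in range(25):
        ref = structs[rng.integers(len(structs))]
        alpha = float(rng.normal(scale=0.7))
        pot = accumulate_potential(pot, ref, alpha)
        refs.append((ref, alpha))
    for s in structs[:50]:
        direct = sum(
            (repellent_penalty_exact(r, s, a) for r, a in refs), Fraction(0)
        )
        assert pot.guiding_term_exact(s) == direct


def test_select_repellent_target_argmax_and_ties():
    a = parse_dotbracket("(((...)))....")
    b = parse_dotbracket("....(((...)))")
    assert select_repellent_target({a: 3, b: 1}) == a
    assert select_repellent_target({b: 2, a: 2}) == a  # lexicographic tie
    assert select_repellent_target({b: 1}) == b
    with pytest.raises(ValueError):
        select_repellent_target({})


def test_saturation_ratio_cases():
    a, b, c = (parse_dotbracket(x) for x in ["(((...)))", "((.....))", "(.......)"])
    bm = BasinMap()
    for s, k in [(a, 3), (b, 1), (c, 1)]:
        bm.add(s, s, 0, k)
    assert saturation_ratio(bm) == pytest.approx(2.0)
    bm2 = BasinMap()
    for s in (a, b):
        bm2.add(s, s, 0, 5)
    assert saturation_ratio(bm2) == 0.0
    bm3 = BasinMap()
    for s in (a, b, c):
        bm3.add(s, s, 0, 1)
    assert saturation_ratio(bm3) == math.inf
    assert saturation_ratio(BasinMap()) == 0.0


def test_single_round_run_is_plain_boltzmann(model, bistable):
    cfg = XplorerConfig(N=100, g=100, seed=5)
    res = run_xplorer(bistable, model, cfg)
    assert len(res.per_round) == 1
    assert res.potential.is_zero() or len(res.potential.history) <= 1
    # the draws must match a plain Boltzmann run with the same derived stream
    pr = partition_function(bistable, model)
    rng = np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0])
    plain = boltzmann_sample(pr, 100, rng)
    assert res.samples.draws == plain.draws


def test_zero_alpha_run_matches_plain_distribution(model, bistable, bistable_exact_p):
    cfg = XplorerConfig(N=20_000, g=100, alpha=0.0, seed=9)
    res = run_xplorer(bistable, model, cfg)
    assert res.potential.is_zero()
    # Z must never be recomputed after round 1 (caching soundness)
    assert sum(1 for r in res.per_round if r.recomputed_Z) == 1
    counts = Counter(res.samples.draws)
    n = len(res.samples)
    tv = 0.5 * sum(abs(counts.get(s, 0) / n - p) for s, p in bistable_exact_p.items())
    assert tv < 0.02


def test_run_is_reproducible(model, bistable):
    cfg = XplorerConfig(N=1000, g=100, seed=21)
    r1 = run_xplorer(bistable, model, cfg)
    r2 = run_xplorer(bistable, model, cfg)
    assert r1.samples.draws == r2.samples.draws
    assert r1.potential.entries == r2.potential.entries
    assert [x.update_applied for x in r1.per_round] == [
        x.update_applied for x in r2.per_round
    ]


def test_replaying_history_reproduces_final_potential(model, bistable):
    res = run_xplorer(bistable, model, XplorerConfig(N=2000, g=100, seed=3))
    replay = PairPotential.replay(
        [(s, float(a)) for s, a in res.potential.history]
    )
    assert replay.entries == res.potential.entries


def test_repelled_minimum_probability_strictly_decreases(
    model, bistable, bistable_enum
):
    beta = model.beta
    pr = partition_function(bistable, model)
    draws = boltzmann_sample(pr, 500, seed=1)
    from rnaxplore import build_basin_map

    bm = build_basin_map(bistable, model, draws)
    target = select_repellent_target(dict(bm.counts))
    alpha = 1.0 / beta  # kT

    def exact_p(pot):
        w = {
            s: math.exp(-beta * (e + float(pot.guiding_term_exact(s)) if pot else e))
            for s, e in bistable_enum
        }
        Z = sum(w.values())
        return w[target] / Z

    p_before = exact_p(PairPotential.zero())
    p_after = exact_p(accumulate_potential(PairPotential.zero(), target, alpha))
    assert p_after < p_before


def test_sampling_follows_current_potential(model, bistable, bistable_enum):
    # mid-run distribution fidelity: draws under an accumulated potential
    # match the exact soft-constrained distribution from enumeration
    beta = model.beta
    target, _ = bistable_enum[0]
    pot = accumulate_potential(PairPotential.zero(), target, 1.0 / beta)
    pr = partition_function(bistable, model, pot)
    n = 20_000
    counts = Counter(boltzmann_sample(pr, n, seed=13).draws)
    w = {s: math.exp(-beta * (e + float(pot.guiding_term_exact(s))))
         for s, e in bistable_enum}
    Z = sum(w.values())
    tv = 0.5 * sum(abs(counts.get(s, 0) / n - v / Z) for s, v in w.items())
    assert tv < 0.02


def test_attractive_potential_increases_reference_mass(model, bistable, bistable_enum):
    beta = model.beta
    from rnaxplore import bistable_helices

    _, right = bistable_helices()
    pot = accumulate_potential(PairPotential.zero(), right, -3.0)  # attract
    w0 = {s: math.exp(-beta * e) for s, e in bistable_enum}
    w1 = {s: math.exp(-beta * (e + float(pot.guiding_term_exact(s))))
          for s, e in bistable_enum}
    p0 = w0[right] / sum(w0.values())
    p1 = w1[right] / sum(w1.values())
    assert p1 > p0


def test_plain_boltzmann_misses_metastable_state_in_majority_of_runs(
    model, bistable, bistable_enum, bistable_exact_p
):
    # exact masses from enumeration: the metastable basin carries so little
    # Boltzmann mass that a plain sample of modest size (N=1000) misses it
    # more often than not
    from rnaxplore import bistable_helices

    _, right = bistable_helices()
    m2 = gradient_walk(bistable, model, right)
    cache = {}
    basin_mass = sum(
        p for s, p in bistable_exact_p.items()
        if gradient_walk(bistable, model, s, cache=cache) == m2
    )
    assert basin_mass < 1e-3
    p_miss = (1.0 - basin_mass) ** 1000
    assert p_miss > 0.5


def test_diversity_dominance_over_plain_boltzmann(model, bistable):
    pr = partition_function(bistable, model)
    from rnaxplore import build_basin_map

    nx, nb = [], []
    for seed in range(10):
        res = run_xplorer(bistable, model, XplorerConfig(N=2000, g=100, seed=seed))
        nx.append(len(res.minima))
        bm = build_basin_map(bistable, model, boltzmann_sample(pr, 2000, seed=seed))
        nb.append(len(bm.counts))
    assert sum(nx) / 10 >= sum(nb) / 10
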