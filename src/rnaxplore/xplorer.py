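"""Iterative Boltzmann sampling with accumulating repellent guiding potentials.

Each round draws ``g`` structures from the current soft-constrained
Boltzmann distribution, gradient-walks them to their local minima, and —
when the cumulative saturation ratio |M1|/|M>1| permits — penalises the
round's most-sampled minimum s' by spreading a weight alpha over its base
pairs (E_ij += alpha/|s'|).  Accumulated over rounds this realises the
local-elevation / metadynamics idea on the discrete RNA landscape: sampling
mass is pushed out of already well-explored basins toward unexplored
regions, while the true landscape (and hence the reported minima) stays
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .energy import EnergyModel, PairPotential
from .landscape import BasinMap, build_basin_map
from .structures import RnaSequence, SecondaryStructure
from .thermo import PartitionResult, SampleSet, boltzmann_sample, partition_function

__all__ = [
    "XplorerConfig",
    "XplorerResult",
    "RoundRecord",
    "repellent_penalty",
    "accumulate_potential",
    "select_repellent_target",
    "saturation_ratio",
    "run_xplorer",
]


@dataclass(frozen=True)
class XplorerConfig:
    """Parameters of the adaptive sampling loop.

    ``alpha=None`` means kT of the model in use (~0.6163 kcal/mol at 37 C).
    ``invert_gate`` flips the saturation criterion for experimentation; the
    default applies the update only while |M1|/|M>1| <= mu.
    """

    N: int = 100_000
    g: int = 100
    alpha: float | None = None
    mu: float = 0.1
    seed: int = 0
    invert_gate: bool = False
    use_potential_in_walks: bool = False

    def __post_init__(self) -> None:
        if not self.N >= self.g >= 1:
            raise ValueError("need N >= g >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.alpha is not None and not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")

    @property
    def m_max(self) -> int:
        return -(-self.N // self.g)


@dataclass(frozen=True)
class RoundRecord:
    round_index: int
    target: SecondaryStructure | None
    saturation: float
    recomputed_Z: bool
    update_applied: bool


@dataclass
class XplorerResult:
    samples: SampleSet
    basin_map: BasinMap
    potential: PairPotential
    per_round: list[RoundRecord]

    @property
    def minima(self) -> set[SecondaryStructure]:
        return set(self.basin_map.counts)


def repellent_penalty(
    ref: SecondaryStructure, s: SecondaryStructure, alpha: float
) -> float:
    """E_c(ref, s) = alpha * |s n ref| / |ref|, the per-structure penalty."""
    return float(repellent_penalty_exact(ref, s, alpha))


def repellent_penalty_exact(
    ref: SecondaryStructure, s: SecondaryStructure, alpha: float | Fraction
) -> Fraction:
    if len(ref.pairs) == 0:
        raise ValueError("repellent reference must contain at least one pair")
    return Fraction(alpha) * len(s.pairs & ref.pairs) / len(ref.pairs)


def accumulate_potential(
    potential: PairPotential, ref: SecondaryStructure, alpha: float
) -> PairPotential:
    """Add alpha/|ref| to E_ij for every (i, j) in ref; history is appended.

    For any structure s the guiding term grows by exactly
    ``repellent_penalty(ref, s, alpha)``.
    """
    return potential.with_update(ref, alpha)


def select_repellent_target(round_basins: dict[SecondaryStructure, int]) -> SecondaryStructure:
    """The local minimum attracting the most samples this round.

    Ties go to the lexicographically smallest dot-bracket, for determinism.
    """
    if not round_basins:
        raise ValueError("no basins observed in this round")
    return min(round_basins, key=lambda s: (-round_basins[s], s.dotbracket))


def saturation_ratio(basin_map: BasinMap) -> float:
    """|M1| / |M>1| over cumulative counts; inf when M>1 is empty but M1 is not."""
    m1 = len(basin_map.singletons())
    mgt = len(basin_map.multiples())
    if mgt == 0:
        return math.inf if m1 > 0 else 0.0
    return m1 / mgt


def run_xplorer(
    seq: RnaSequence,
    model: EnergyModel,
    cfg: XplorerConfig,
    initial_potential: PairPotential | None = None,
) -> XplorerResult:
    """Run the full adaptive sampling loop; reproducible from (seq, model, cfg).

    Per round: recompute Z only if the potential changed; draw g samples;
    map them to gradient-basin minima of the unmodified landscape; pick the
    round's dominant minimum; apply the repellent update when the cumulative
    saturation ratio passes the gate.  Open-chain targets are skipped (the
    penalty is undefined for |ref| = 0).
    """
    alpha = cfg.alpha
    if alpha is None:
        alpha = 1.0 / model.beta
    pot = initial_potential if initial_potential is not None else PairPotential.zero()
    pot_dirty = True
    pr: PartitionResult | None = None
    bm = BasinMap()
    walk_cache: dict[SecondaryStructure, SecondaryStructure] = {}
    per_round: list[RoundRecord] = []
    draws: list[SecondaryStructure] = []

    ss_master = np.random.SeedSequence(cfg.seed)
    round_seeds = ss_master.spawn(cfg.m_max)

    remaining = cfg.N
    for m in range(1, cfg.m_max + 1):
        g_m = min(cfg.g, remaining)
        remaining -= g_m
        recomputed = False
        if pot_dirty or pr is None:
            pr = partition_function(seq, model, None if pot.is_zero() else pot)
            pot_dirty = False
            recomputed = True
        rng = np.random.default_rng(round_seeds[m - 1])
        round_samples = boltzmann_sample(pr, g_m, rng, source=f"xplorer round {m}")
        draws.extend(round_samples.draws)
        build_basin_map(
            seq, model, round_samples,
            potential=pot if cfg.use_potential_in_walks else None,
            cache=walk_cache, round_index=m, into=bm,
        )
        round_counts = dict(bm.round_counts[m])
        target = select_repellent_target(round_counts)
        ratio = saturation_ratio(bm)
        gate = (ratio <= cfg.mu) if not cfg.invert_gate else (ratio > cfg.mu)
        applied = False
        if gate and len(target.pairs) > 0:
            pot = accumulate_potential(pot, target, alpha)
            if alpha != 0:
                pot_dirty = True
            applied = True
        per_round.append(
            RoundRecord(m, target if applied else None, ratio, recomputed, applied)
        )

    samples = SampleSet(tuple(draws), cfg.seed, "xplorer")
    return XplorerResult(samples, bm, pot, per_round)
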