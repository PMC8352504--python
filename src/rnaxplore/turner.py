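"""Optional Turner nearest-neighbor backend via the ViennaRNA bindings.

The adapter evaluates structures under the full Turner model and performs
MFE folding, partition-function computation and Boltzmann sampling with the
per-pair guiding potential injected through ViennaRNA's soft-constraint
layer.  Its loop terms are not decomposable into the pair+stack form
consumed by the in-repo dynamic programs, so it drives ViennaRNA's own DP
instead; the self-contained bpstack model remains the default everywhere.
Requires the ``RNA`` python module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import DEFAULT_TEMPERATURE, GAS_CONSTANT, PairPotential, to_centikcal
from .structures import RnaSequence, SecondaryStructure, parse_dotbracket
from .thermo import SampleSet

__all__ = ["TurnerModel", "turner_mfe", "turner_sample"]


def _rna():
    import RNA  # deferred: optional dependency

    return RNA


def _fold_compound(seq: RnaSequence, potential: PairPotential | None, temperature: float):
    RNA = _rna()
    md = RNA.md()
    md.temperature = temperature - 273.15
    md.uniq_ML = 1
    fc = RNA.fold_compound(seq.residues, md)
    if potential is not None:
        for (i, j), v in sorted(potential.entries.items()):
            fc.sc_add_bp(i, j, float(v))
    return fc


@dataclass(frozen=True)
class TurnerModel:
    """Turner free-energy evaluation through ViennaRNA.

    Satisfies the evaluation side of the energy-backend contract; the
    loop-decomposable terms of the pair+stack interface are not available,
    so this model cannot feed the in-repo DP tables.
    """

    name: str = "turner"
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def kT(self) -> float:
        return GAS_CONSTANT * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @property
    def stack_bonus_c(self) -> int:
        raise NotImplementedError("Turner terms are not pair+stack decomposable")

    def pair_energy_c(self, seq: RnaSequence, i: int, j: int) -> int | None:
        raise NotImplementedError("Turner terms are not pair+stack decomposable")

    def structure_energy_c(self, seq: RnaSequence, s: SecondaryStructure) -> int:
        fc = _fold_compound(seq, None, self.temperature)
        return to_centikcal(fc.eval_structure(s.dotbracket))


def turner_mfe(
    seq: RnaSequence,
    potential: PairPotential | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[SecondaryStructure, float]:
    fc = _fold_compound(seq, potential, temperature)
    db, e = fc.mfe()
    return parse_dotbracket(db), e


def turner_sample(
    seq: RnaSequence,
    count: int,
    seed: int,
    potential: PairPotential | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> SampleSet:
    """Boltzmann sampling under the Turner model plus guiding potential."""
    RNA = _rna()
    RNA.init_rand(int(seed))
    fc = _fold_compound(seq, potential, temperature)
    fc.exp_params_rescale(fc.mfe()[1])
    fc.pf()
    draws = tuple(parse_dotbracket(db) for db in fc.pbacktrack(count))
    return SampleSet(draws, seed, "turner-boltzmann")
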