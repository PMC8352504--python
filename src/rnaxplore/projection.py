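"""2D distance-class projection of structure ensembles.

Relative to two reference structures, every structure falls into exactly one
class C(d1, d2) with d1, d2 its base-pair distances to the references.  Each
class is summarised by its minimum energy (class MFE) and the ensemble free
energy G = -kT ln sum exp(-beta E).  Coverage counts the truth classes that
a sample set hits within an energy margin theta of the true class MFE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .energy import EnergyModel, PairPotential
from .structures import RnaSequence, SecondaryStructure, base_pair_distance
from .thermo import mfe_fold

__all__ = [
    "Cell",
    "DistanceClassGrid",
    "DegenerateReferenceError",
    "reference_pair",
    "project",
    "class_coverage",
]


class DegenerateReferenceError(ValueError):
    """The MFE structure has no pairs, so no reference pair exists."""


@dataclass
class Cell:
    best_energy: float
    best_structure: SecondaryStructure
    Zsum: float = 0.0
    count: int = 0


@dataclass
class DistanceClassGrid:
    """Sparse (d1, d2) -> class summary grid for a structure collection."""

    s1: SecondaryStructure
    s2: SecondaryStructure
    beta: float
    cells: dict[tuple[int, int], Cell] = field(default_factory=dict)
    source: str = "sampled"

    def free_energy(self, d1: int, d2: int) -> float:
        """G(d1, d2) = -(1/beta) ln Zsum of the cell."""
        c = self.cells[(d1, d2)]
        return -math.log(c.Zsum) / self.beta

    def occupied(self) -> set[tuple[int, int]]:
        return set(self.cells)


def reference_pair(
    seq: RnaSequence, model: EnergyModel
) -> tuple[SecondaryStructure, SecondaryStructure]:
    """The MFE structure and the most stable structure sharing none of its pairs.

    The second reference comes from a constrained fold in which every base
    pair of the MFE structure is prohibited, so the two share no pair by
    construction.
    """
    s1, _ = mfe_fold(seq, model)
    if len(s1.pairs) == 0:
        raise DegenerateReferenceError(
            f"MFE structure of {seq.id} is the open chain; references are degenerate"
        )
    s2, _ = mfe_fold(seq, model, forbidden=s1.pairs)
    return s1, s2


def project(
    structures: Iterable[tuple[SecondaryStructure, float]],
    s1: SecondaryStructure,
    s2: SecondaryStructure,
    beta: float,
    source: str = "sampled",
) -> DistanceClassGrid:
    """Assign each (structure, energy) to its distance class and summarise.

    Duplicate structures in the input accumulate in Zsum and count but do
    not change the class minimum.
    """
    grid = DistanceClassGrid(s1, s2, beta, source=source)
    for s, e in structures:
        d1 = base_pair_distance(s, s1)
        d2 = base_pair_distance(s, s2)
        cell = grid.cells.get((d1, d2))
        if cell is None:
            grid.cells[(d1, d2)] = cell = Cell(e, s)
        elif (e, s.dotbracket) < (cell.best_energy, cell.best_structure.dotbracket):
            cell.best_energy = e
            cell.best_structure = s
        cell.Zsum += math.exp(-beta * e)
        cell.count += 1
    return grid


def class_coverage(
    sampled: DistanceClassGrid,
    truth: DistanceClassGrid,
    theta: float = 0.0,
    use_free_energy: bool = False,
) -> float:
    """Fraction of occupied truth classes covered by the sample within theta.

    A truth class is covered when the sample occupies it and the sample's
    class minimum lies within ``theta`` kcal/mol of the true class MFE
    (or, with ``use_free_energy``, when the class free energies G agree
    within theta).  The denominator is the number of occupied truth classes.
    """
    if (sampled.s1, sampled.s2) != (truth.s1, truth.s2):
        raise ValueError("grids use different reference structures")
    denom = len(truth.cells)
    if denom == 0:
        return 0.0
    covered = 0
    for key, tcell in truth.cells.items():
        scell = sampled.cells.get(key)
        if scell is None:
            continue
        if use_free_energy:
            gap = sampled.free_energy(*key) - truth.free_energy(*key)
        else:
            gap = scell.best_energy - tcell.best_energy
        if gap <= theta + 1e-12:
            covered += 1
    return covered / denom
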