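"""Energy models and the soft-constraint pseudo-energy layer.

The energy of a structure s is E(s); a guiding potential adds a pair-additive
pseudo-energy  E_psi(s) = sum_{(i,j) in s} E_ij  so the effective energy is
Ehat(s) = E(s) + E_psi(s).  Model energies are held as integers in units of
10^-2 kcal/mol so comparisons and gradient-walk tie-breaking are exact and
platform-independent; potential entries are exact rationals so the closed
form E_ij = sum_l alpha_l * delta_ij(s'_l) / |s'_l| holds bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Protocol, runtime_checkable

from .structures import RnaSequence, SecondaryStructure, StructureError

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "EnergyModel",
    "BpStackModel",
    "PairPotential",
    "structure_energy",
    "guiding_term",
    "to_centikcal",
]

#: gas constant in kcal/(mol K)
GAS_CONSTANT = 1.98717e-3

#: 37 degrees Celsius, the standard folding temperature
DEFAULT_TEMPERATURE = 310.15


def to_centikcal(x: float) -> int:
    """Round a kcal/mol value to integer centi-kcal/mol, half away from zero."""
    return int(math.floor(abs(x) * 100 + 0.5)) * (1 if x >= 0 else -1)


@runtime_checkable
class EnergyModel(Protocol):
    """Pluggable energy backend.

    A model must expose loop-decomposable terms consumable by the dynamic
    programs in :mod:`rnaxplore.thermo`: a per-pair contribution and a bonus
    for each stacked adjacency ((i,j) and (i+1,j-1) both paired), plus the
    inverse temperature.  The open chain has energy 0 exactly.
    """

    name: str
    temperature: float

    @property
    def beta(self) -> float: ...

    def pair_energy_c(self, seq: RnaSequence, i: int, j: int) -> int | None:
        """Centi-kcal energy of pair (i, j) on seq, or None if disallowed."""
        ...

    @property
    def stack_bonus_c(self) -> int: ...

    def structure_energy_c(self, seq: RnaSequence, s: SecondaryStructure) -> int: ...


@dataclass(frozen=True)
class BpStackModel:
    """Built-in base-pair + stacking model, the self-contained testing default.

    E(s) = sum over pairs of e_pair + stack_bonus per stacked adjacency, with
    e_pair(GC/CG) = -3.0, e_pair(AU/UA) = -2.0, e_pair(GU/UG) = -1.0 and
    stack_bonus = -1.0 kcal/mol.  These constants are a design choice of this
    package, not measured parameters; they produce rugged, enumerable
    landscapes on short sequences.
    """

    name: str = "bpstack"
    temperature: float = DEFAULT_TEMPERATURE
    gc_energy: float = -3.0
    au_energy: float = -2.0
    gu_energy: float = -1.0
    stack_bonus: float = -1.0

    @property
    def kT(self) -> float:
        return GAS_CONSTANT * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @property
    def stack_bonus_c(self) -> int:
        return to_centikcal(self.stack_bonus)

    def pair_energy_c(self, seq: RnaSequence, i: int, j: int) -> int | None:
        if not seq.can_pair(i, j):
            return None
        a, b = seq[i], seq[j]
        if {a, b} == {"G", "C"}:
            return to_centikcal(self.gc_energy)
        if {a, b} == {"A", "U"}:
            return to_centikcal(self.au_energy)
        return to_centikcal(self.gu_energy)

    def structure_energy_c(self, seq: RnaSequence, s: SecondaryStructure) -> int:
        total = 0
        for i, j in s.pairs:
            e = self.pair_energy_c(seq, i, j)
            if e is None:
                raise StructureError(f"pair {(i, j)} not allowed by model on {seq.id}")
            total += e
        total += self.stack_bonus_c * s.stacked_adjacencies()
        return total


@dataclass(frozen=True)
class PairPotential:
    """Per-base-pair pseudo-energy matrix E_ij (kcal/mol), with history.

    ``entries`` maps (i, j) (1-based, i < j) to exact rational energies;
    ``history`` records each applied (reference structure, alpha) update so
    the matrix is reconstructible from scratch.
    """

    entries: dict[tuple[int, int], Fraction] = field(default_factory=dict)
    history: tuple[tuple[SecondaryStructure, Fraction], ...] = ()

    @classmethod
    def zero(cls) -> "PairPotential":
        return cls()

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[int, int, float]]
    ) -> "PairPotential":
        """Build a potential from (i, j, E_ij in kcal/mol) triples."""
        d: dict[tuple[int, int], Fraction] = {}
        for i, j, e in entries:
            if not 1 <= i < j:
                raise StructureError(f"potential entry must have 1 <= i < j: {(i, j)}")
            if e != 0:
                d[(i, j)] = d.get((i, j), Fraction(0)) + Fraction(e)
        return cls({k: v for k, v in d.items() if v != 0})

    def entry(self, i: int, j: int) -> Fraction:
        return self.entries.get((i, j), Fraction(0))

    def is_zero(self) -> bool:
        return not self.entries

    def guiding_term_exact(self, s: SecondaryStructure) -> Fraction:
        """E_psi(s) = sum of E_ij over pairs present in s, as an exact rational."""
        if not self.entries:
            return Fraction(0)
        return sum((self.entries[p] for p in s.pairs if p in self.entries), Fraction(0))

    def with_update(self, ref: SecondaryStructure, alpha: float) -> "PairPotential":
        """Return a new potential with E_ij += alpha/|ref| for (i, j) in ref."""
        if len(ref.pairs) == 0:
            raise StructureError("repellent reference must contain at least one pair")
        alpha_f = Fraction(alpha)
        inc = alpha_f / len(ref.pairs)
        entries = dict(self.entries)
        for p in sorted(ref.pairs):
            v = entries.get(p, Fraction(0)) + inc
            if v == 0:
                entries.pop(p, None)
            else:
                entries[p] = v
        return PairPotential(entries, self.history + ((ref, alpha_f),))

    @classmethod
    def replay(cls, history: Iterable[tuple[SecondaryStructure, float]]) -> "PairPotential":
        """Rebuild a potential by replaying an update history from zero."""
        pot = cls.zero()
        for ref, alpha in history:
            pot = pot.with_update(ref, alpha)
        return pot


def guiding_term(potential: PairPotential | None, s: SecondaryStructure) -> float:
    """E_psi(s) in kcal/mol; 0 for the zero/absent potential."""
    if potential is None:
        return 0.0
    return float(potential.guiding_term_exact(s))


def structure_energy(
    model: EnergyModel,
    seq: RnaSequence,
    s: SecondaryStructure,
    potential: PairPotential | None = None,
) -> float:
    """Ehat(s) = E(s) + E_psi(s) in kcal/mol (E(s) alone if no potential)."""
    s.validate_on(seq)
    e = model.structure_energy_c(seq, s) / 100.0
    return e + guiding_term(potential, s)


def structure_energy_exact(
    model: EnergyModel,
    seq: RnaSequence,
    s: SecondaryStructure,
    potential: PairPotential | None = None,
) -> Fraction:
    """Ehat(s) as an exact rational (kcal/mol), for tie-breaking."""
    e = Fraction(model.structure_energy_c(seq, s), 100)
    if potential is not None:
        e += potential.guiding_term_exact(s)
    return e
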