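"""Dynamic programming over the (soft-constrained) energy model.

Two-table recursions on intervals [i, j] (1-based, inclusive):

* ``Q[i][j]``   — all structures on the interval (including the empty one),
* ``Qp[i][j]``  — structures in which (i, j) is paired,
* ``Qns[i][j]`` — structures in which (i, j) is *not* paired,

with ``Q = Qp + Qns``.  The pair term carries the model's pair energy plus
the guiding-potential entry E_ij, the stacking bonus is routed through the
paired table, which keeps the pseudo-energy exactly pair-additive.  The
partition function is computed in a scaled linear domain (a per-nucleotide
scale factor derived from the MFE) so that Z never overflows for sequences
of several hundred nucleotides; sampling probabilities are scale-free
ratios.  Stochastic backtracking draws i.i.d. structures from
p(s) = exp(-beta*Ehat(s)) / Z.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np

from .energy import EnergyModel, PairPotential, structure_energy
from .structures import RnaSequence, SecondaryStructure, StructureError

__all__ = [
    "PartitionResult",
    "SampleSet",
    "mfe_fold",
    "partition_function",
    "boltzmann_sample",
    "uniform_sample",
    "enumerate_structures",
    "EnumerationCeilingError",
    "DEFAULT_ENUMERATION_CEILING",
]

DEFAULT_ENUMERATION_CEILING = 5_000_000

_INF = float("inf")


class EnumerationCeilingError(RuntimeError):
    """Raised when exhaustive enumeration exceeds the structure-count ceiling."""


def _pair_tables(
    seq: RnaSequence,
    model: EnergyModel,
    potential: PairPotential | None,
    forbidden: frozenset[tuple[int, int]] | None,
):
    """Per-pair centi-kcal energies (exact rationals if a potential is set).

    Returns (pairval, partners) where pairval[(i, j)] is the energy of
    forming (i, j) and partners[j] lists the admissible k < j, ascending.
    """
    n = seq.n
    pairval: dict[tuple[int, int], int | Fraction] = {}
    partners: list[list[int]] = [[] for _ in range(n + 1)]
    for j in range(1, n + 1):
        for i in range(1, j):
            if forbidden and ((i, j) in forbidden or (j, i) in forbidden):
                continue
            e = model.pair_energy_c(seq, i, j)
            if e is None:
                continue
            v: int | Fraction = e
            if potential is not None:
                p = potential.entry(i, j)
                if p != 0:
                    v = e + p * 100
            pairval[(i, j)] = v
            partners[j].append(i)
    return pairval, partners


# ---------------------------------------------------------------------------
# MFE folding
# ---------------------------------------------------------------------------

def mfe_fold(
    seq: RnaSequence,
    model: EnergyModel,
    potential: PairPotential | None = None,
    forbidden: frozenset[tuple[int, int]] | set[tuple[int, int]] | None = None,
) -> tuple[SecondaryStructure, float]:
    """Minimum-(pseudo-)energy structure and its energy in kcal/mol.

    ``forbidden`` pairs are excluded from the fold (hard constraint).  Among
    co-optimal structures the lexicographically smallest dot-bracket is
    returned, which makes the fold deterministic.  The open chain (energy 0)
    is always feasible.
    """
    forb = frozenset(forbidden) if forbidden else None
    pairval, partners = _pair_tables(seq, model, potential, forb)
    n = seq.n
    sb = model.stack_bonus_c

    # E[(i, j)]: min over all structures; Ens excludes (i, j) paired;
    # Ep requires it.  Empty intervals have energy 0.
    E: dict[tuple[int, int], int | Fraction] = {}
    Ens: dict[tuple[int, int], int | Fraction] = {}
    Ep: dict[tuple[int, int], int | Fraction] = {}

    def get_E(i: int, j: int):
        return E[(i, j)] if i <= j else 0

    for span in range(1, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            if (i, j) in pairval:
                inner_ns = Ens.get((i + 1, j - 1), 0)
                inner = inner_ns
                ip = Ep.get((i + 1, j - 1))
                if ip is not None and sb + ip < inner:
                    inner = sb + ip
                Ep[(i, j)] = pairval[(i, j)] + inner
            best = get_E(i, j - 1)  # j unpaired
            for k in partners[j]:
                if k <= i:
                    continue
                cand = get_E(i, k - 1) + Ep[(k, j)]
                if cand < best:
                    best = cand
            Ens[(i, j)] = best
            ep = Ep.get((i, j))
            E[(i, j)] = ep if ep is not None and ep < best else best

    # lexicographically smallest optimal structure, by memoized reconstruction;
    # '(' < ')' < '.' in byte order, so candidates are compared as full strings
    memo: dict[tuple[str, int, int], str] = {}

    def rec(kind: str, i: int, j: int) -> str:
        if i > j:
            return ""
        key = (kind, i, j)
        if key in memo:
            return memo[key]
        cands: list[str] = []
        if kind == "P":
            opt = Ep[(i, j)] - pairval[(i, j)]
            ip = Ep.get((i + 1, j - 1))
            if ip is not None and sb + ip == opt:
                cands.append(rec("P", i + 1, j - 1))
            if Ens.get((i + 1, j - 1), 0) == opt:
                cands.append(rec("X", i + 1, j - 1))
            out = "(" + min(cands) + ")"
        else:
            opt = E[(i, j)] if kind == "Q" else Ens[(i, j)]
            if get_E(i, j - 1) == opt:
                cands.append(rec("Q", i, j - 1) + ".")
            kmin = i if kind == "Q" else i + 1
            for k in partners[j]:
                if k < kmin:
                    continue
                if get_E(i, k - 1) + Ep[(k, j)] == opt:
                    cands.append(rec("Q", i, k - 1) + rec("P", k, j))
            out = min(cands)
        memo[key] = out
        return out

    if n == 0 or (1, n) not in E:
        return SecondaryStructure.open_chain(n), 0.0
    db = rec("Q", 1, n)
    from .structures import parse_dotbracket

    s = parse_dotbracket(db)
    return s, float(E[(1, n)]) / 100.0


# ---------------------------------------------------------------------------
# Partition function
# ---------------------------------------------------------------------------

@dataclass
class PartitionResult:
    """DP tables and Z for a (sequence, model, potential) triple.

    ``Q``/``Qp``/``Qns`` are scaled by ``scale**(interval length)``; ``Z``
    is unscaled (may be ``inf`` for extreme inputs, ``log_Z`` never is).
    """

    seq: RnaSequence
    model: EnergyModel
    potential: PairPotential | None
    beta: float
    scale: float
    Q: np.ndarray
    Qp: np.ndarray
    Qns: np.ndarray
    _wpair: dict[tuple[int, int], float]
    _partners: list[list[int]]
    _stack_w: float
    _choices: dict = field(default_factory=dict, repr=False)

    @property
    def log_Z(self) -> float:
        n = self.seq.n
        return math.log(self.Q[1, n]) - n * math.log(self.scale)

    @property
    def Z(self) -> float:
        try:
            return math.exp(self.log_Z)
        except OverflowError:
            return _INF


def partition_function(
    seq: RnaSequence,
    model: EnergyModel,
    potential: PairPotential | None = None,
    beta: float | None = None,
) -> PartitionResult:
    """Z = sum over all structures of exp(-beta * Ehat(s)), by DP.

    ``beta`` overrides the model's inverse temperature (``beta=0`` gives the
    uniform ensemble).  O(n^3) time, O(n^2) space.
    """
    if beta is None:
        beta = model.beta
    pairval, partners = _pair_tables(seq, model, potential, None)
    n = seq.n
    sw = math.exp(-beta * model.stack_bonus_c / 100.0)

    # per-nucleotide scale from a quick MFE estimate, so Q stays representable
    scale = 1.0
    if beta > 0 and pairval:
        _, e_mfe = mfe_fold(seq, model, potential)
        if e_mfe < 0:
            scale = math.exp(beta * e_mfe / n)

    w = {p: math.exp(-beta * float(v) / 100.0) for p, v in pairval.items()}

    Q = np.zeros((n + 2, n + 1))
    Qp = np.zeros((n + 2, n + 1))
    Qns = np.zeros((n + 2, n + 1))
    for i in range(1, n + 2):
        if i - 1 <= n:
            Q[i, i - 1] = 1.0  # empty interval
    s2 = scale * scale
    for span in range(1, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            if (i, j) in w:
                Qp[i, j] = w[(i, j)] * s2 * (
                    sw * Qp[i + 1, j - 1] + (Qns[i + 1, j - 1] if j - 1 >= i + 1 else Q[i + 1, j - 1])
                )
            acc = Q[i, j - 1] * scale  # j unpaired
            for k in partners[j]:
                if k <= i:
                    continue
                acc += Q[i, k - 1] * Qp[k, j]
            Qns[i, j] = acc
            Q[i, j] = acc + Qp[i, j]
    return PartitionResult(
        seq, model, potential, beta, scale, Q, Qp, Qns, w, partners, sw
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSet:
    """A multiset of sampled structures, in draw order."""

    draws: tuple[SecondaryStructure, ...]
    seed: int | None
    source: str

    def __len__(self) -> int:
        return len(self.draws)

    def __iter__(self) -> Iterator[SecondaryStructure]:
        return iter(self.draws)

    def counts(self) -> Counter:
        return Counter(self.draws)

    def unique(self) -> list[SecondaryStructure]:
        return list(dict.fromkeys(self.draws))


def _choice_table(pr: PartitionResult, kind: str, i: int, j: int):
    """Cumulative option weights for backtracking state (kind, i, j)."""
    key = (kind, i, j)
    tab = pr._choices.get(key)
    if tab is not None:
        return tab
    Q, Qp = pr.Q, pr.Qp
    opts: list[tuple] = []
    weights: list[float] = []
    if kind == "P":
        if j - 1 >= i + 1:
            weights.append(pr._stack_w * Qp[i + 1, j - 1])
            opts.append(("s",))
            weights.append(pr.Qns[i + 1, j - 1])
            opts.append(("n",))
        else:
            weights.append(Q[i + 1, j - 1] if i + 1 <= j else 1.0)
            opts.append(("n",))
    else:
        weights.append(Q[i, j - 1] * pr.scale)
        opts.append(("u",))
        kmin = i if kind == "Q" else i + 1
        for k in pr._partners[j]:
            if k < kmin:
                continue
            wk = Q[i, k - 1] * Qp[k, j]
            if wk > 0:
                weights.append(wk)
                opts.append(("p", k))
    cum = np.cumsum(weights)
    tab = (cum, opts)
    pr._choices[key] = tab
    return tab


def _backtrack_one(pr: PartitionResult, rng: np.random.Generator) -> SecondaryStructure:
    n = pr.seq.n
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("Q", 1, n)]
    while stack:
        kind, i, j = stack.pop()
        if i >= j:
            continue
        if kind == "P":
            pairs.append((i, j))
            cum, opts = _choice_table(pr, "P", i, j)
            r = rng.random() * cum[-1]
            op = opts[int(np.searchsorted(cum, r, side="right"))]
            if op[0] == "s":
                stack.append(("P", i + 1, j - 1))
            else:
                stack.append(("X", i + 1, j - 1))
        else:
            cum, opts = _choice_table(pr, kind, i, j)
            r = rng.random() * cum[-1]
            op = opts[int(np.searchsorted(cum, r, side="right"))]
            if op[0] == "u":
                stack.append(("Q", i, j - 1))
            else:
                k = op[1]
                stack.append(("P", k, j))
                stack.append(("Q", i, k - 1))
    return SecondaryStructure.from_pairs(pairs, n)


def boltzmann_sample(
    pr: PartitionResult,
    count: int,
    seed: int | np.random.Generator,
    source: str = "boltzmann",
) -> SampleSet:
    """Draw ``count`` i.i.d. structures from p(s) = exp(-beta*Ehat(s))/Z.

    Identical (pr, count, seed) reproduce the identical multiset.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng, seed_val = seed, None
    else:
        rng, seed_val = np.random.default_rng(seed), seed
    draws = tuple(_backtrack_one(pr, rng) for _ in range(count))
    return SampleSet(draws, seed_val, source)


def uniform_sample(
    seq: RnaSequence,
    model: EnergyModel,
    count: int,
    seed: int,
) -> SampleSet:
    """Uniform draws over all valid structures (the infinite-temperature limit)."""
    pr = partition_function(seq, model, None, beta=0.0)
    ss = boltzmann_sample(pr, count, seed, source="uniform")
    return ss


# ---------------------------------------------------------------------------
# Exhaustive enumeration
# ---------------------------------------------------------------------------

def enumerate_structures(
    seq: RnaSequence,
    model: EnergyModel,
    band: float | None = None,
    potential: PairPotential | None = None,
    ceiling: int = DEFAULT_ENUMERATION_CEILING,
) -> list[tuple[SecondaryStructure, float]]:
    """All valid structures with energies, sorted by (energy, dot-bracket).

    ``band`` keeps only structures within that many kcal/mol above the
    minimum; ``None`` keeps all of Omega.  Intended for short sequences; an
    :class:`EnumerationCeilingError` names the count when ``ceiling`` is hit.
    """
    n = seq.n
    allowed: dict[int, list[int]] = {j: [] for j in range(1, n + 1)}
    for j in range(1, n + 1):
        for i in range(1, j):
            if model.pair_energy_c(seq, i, j) is not None:
                allowed[j].append(i)
    by_i: dict[int, list[int]] = {i: [] for i in range(1, n + 1)}
    for j, ks in allowed.items():
        for i in ks:
            by_i[i].append(j)

    produced = 0

    def gen(i: int, j: int):
        """Yield pair tuples for interval [i, j]; decomposition on i."""
        nonlocal produced
        if j - i < 4:
            yield ()
            return
        for rest in gen(i + 1, j):
            yield rest
        for k in by_i[i]:
            if k > j:
                break
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield inner + ((i, k),) + outer

    out: list[tuple[SecondaryStructure, float]] = []
    for pairs in gen(1, n):
        produced += 1
        if produced > ceiling:
            raise EnumerationCeilingError(
                f"enumeration exceeded ceiling of {ceiling} structures"
            )
        s = SecondaryStructure.from_pairs(pairs, n)
        out.append((s, structure_energy(model, seq, s, potential)))
    out.sort(key=lambda t: (t[1], t[0].dotbracket))
    if band is not None:
        e0 = out[0][1]
        out = [t for t in out if t[1] <= e0 + band + 1e-12]
    return out
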