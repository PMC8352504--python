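"""Diversity measures for structure ensembles.

Density of states (unique structures per energy bin), weighted mean
base-pair distance (the Boltzmann-weighted expected pairwise distance) and
unique-structure/minima counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structures import SecondaryStructure

__all__ = [
    "DiversityReport",
    "density_of_states",
    "weighted_mean_bp_distance",
    "diversity_report",
    "sample_fit",
]


@dataclass(frozen=True)
class DiversityReport:
    n_samples: int
    n_unique_structures: int
    n_unique_minima: int
    dos: dict[float, int]
    weighted_mean_bp_distance: float


def _unique(items: Iterable[tuple[SecondaryStructure, float]]):
    seen: dict[SecondaryStructure, float] = {}
    for s, e in items:
        if s not in seen:
            seen[s] = e
    return list(seen.items())


def density_of_states(
    items: Sequence[tuple[SecondaryStructure, float]],
    bin_width: float = 1.0,
) -> dict[float, int]:
    """Histogram of unique structures per energy bin.

    Bins are half-open [lo, lo + w), anchored at the minimum energy; keys
    are the bin lower edges.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    uni = _unique(items)
    if not uni:
        raise ValueError("empty input")
    e0 = min(e for _, e in uni)
    hist: dict[float, int] = {}
    for _, e in uni:
        k = int((e - e0) / bin_width + 1e-12)
        lo = e0 + k * bin_width
        hist[lo] = hist.get(lo, 0) + 1
    return dict(sorted(hist.items()))


def weighted_mean_bp_distance(
    unique: Sequence[tuple[SecondaryStructure, float]],
    beta: float,
) -> float:
    """Expected base-pair distance under renormalised Boltzmann weights.

    With w(s) = exp(-beta E(s)) normalised over the input set, this is
    sum_{s,t} w(s) w(t) d(s,t), evaluated through the pair-frequency
    identity sum_{(i,j)} 2 q_ij (1 - q_ij) with q_ij the weighted frequency
    of pair (i, j) — identical to the double sum but linear in input size.
    """
    uni = _unique(unique)
    if not uni:
        raise ValueError("empty input")
    energies = np.array([e for _, e in uni], dtype=float)
    logw = -beta * energies
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    q: dict[tuple[int, int], float] = {}
    for (s, _), ws in zip(uni, w):
        for p in s.pairs:
            q[p] = q.get(p, 0.0) + ws
    return float(sum(2.0 * qi * (1.0 - qi) for qi in q.values()))


def sample_fit(
    counts: dict[SecondaryStructure, int],
    probs: dict[SecondaryStructure, float],
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Compare empirical draw counts against an exact distribution.

    Returns (total-variation distance, chi-square p-value); expected counts
    below ``min_expected`` are pooled into one class before the test.
    """
    from scipy import stats

    n = sum(counts.values())
    tv = 0.5 * sum(abs(counts.get(s, 0) / n - p) for s, p in probs.items())
    tv += 0.5 * sum(c / n for s, c in counts.items() if s not in probs)
    obs_main, exp_main = [], []
    obs_pool = exp_pool = 0.0
    for s, p in probs.items():
        e = n * p
        o = counts.get(s, 0)
        if e < min_expected:
            obs_pool += o
            exp_pool += e
        else:
            obs_main.append(o)
            exp_main.append(e)
    if exp_pool > 0:
        obs_main.append(obs_pool)
        exp_main.append(exp_pool)
    obs = np.asarray(obs_main, dtype=float)
    exp = np.asarray(exp_main, dtype=float)
    exp *= obs.sum() / exp.sum()
    if len(obs) < 2:
        return tv, 1.0
    _, pval = stats.chisquare(obs, exp)
    return tv, float(pval)


def diversity_report(
    samples: Sequence[tuple[SecondaryStructure, float]],
    minima: Iterable[SecondaryStructure],
    beta: float,
    bin_width: float = 1.0,
) -> DiversityReport:
    uni = _unique(samples)
    return DiversityReport(
        n_samples=len(samples),
        n_unique_structures=len(uni),
        n_unique_minima=len(set(minima)),
        dos=density_of_states(samples, bin_width),
        weighted_mean_bp_distance=weighted_mean_bp_distance(uni, beta),
    )
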