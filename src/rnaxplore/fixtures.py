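"""Sequence generators: uniform random RNAs and a designed bistable switch."""

from __future__ import annotations

import numpy as np

from .structures import RnaSequence, SecondaryStructure

__all__ = [
    "generate_random_sequences",
    "generate_bistable_fixture",
    "bistable_helices",
]

_BASES = np.array(list("ACGU"))


def generate_random_sequences(
    count: int, length: int, seed: int
) -> list[RnaSequence]:
    """``count`` i.i.d. sequences with equal probability for each nucleotide."""
    if count < 1 or length < 1:
        raise ValueError("count and length must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(count):
        res = "".join(rng.choice(_BASES, size=length))
        out.append(RnaSequence(res, id=f"rnd{length}-{k}"))
    return out


def _bistable_parts(helix_len: int) -> tuple[str, str, str]:
    # arm X: G followed by an alternating A/C run (the mixed arm locks the
    # helix register); tail T weakens every C of X to a wobble U
    x = "G" + "".join("A" if t % 2 == 0 else "C" for t in range(helix_len - 1))
    comp = {"A": "U", "C": "G", "G": "C"}
    m = "".join(comp[c] for c in reversed(x))
    t = x.replace("C", "U")
    return x, m, t


def generate_bistable_fixture(helix_len: int = 4, linker: int = 3) -> RnaSequence:
    """A two-state switch sequence with mutually exclusive helices.

    Layout ``X A^l M A^l T`` with X a mixed G/A/C arm, M its reverse
    complement and T a weakened copy of X (C replaced by wobble U).  The
    central tract M pairs either upstream with X (Watson-Crick, the stable
    state) or downstream with T (partly wobble, the metastable state).  The
    two helices share M, so they are mutually exclusive, and mixing their
    pairs would cross; the mixed arm locks the helix registers.  Under the
    built-in pair+stack model the metastable helix basin carries only a
    small Boltzmann mass (about 7e-4 at the defaults), so plain sampling
    rarely visits it while repellent sampling surfaces it reliably.
    """
    if helix_len < 4:
        raise ValueError("helix_len must be >= 4")
    x, m, t = _bistable_parts(helix_len)
    res = x + "A" * linker + m + "A" * linker + t
    return RnaSequence(res, id=f"bistable-h{helix_len}-l{linker}")


def bistable_helices(
    helix_len: int = 4, linker: int = 3
) -> tuple[SecondaryStructure, SecondaryStructure]:
    """The two designed helices of :func:`generate_bistable_fixture`."""
    h, l = helix_len, linker
    n = 3 * h + 2 * l
    left = SecondaryStructure.from_pairs(
        [(h + 1 - t, h + l + t) for t in range(1, h + 1)], n
    )
    right = SecondaryStructure.from_pairs(
        [(2 * h + l + 1 - t, 2 * h + 2 * l + t) for t in range(1, h + 1)], n
    )
    return left, right
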