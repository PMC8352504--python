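"""RNA sequences and pseudoknot-free secondary structures.

A secondary structure is a set of canonical base pairs (i, j), 1-based with
i < j, such that every position pairs at most once, pair intervals are nested
or disjoint (no pseudoknots) and every hairpin loop contains at least three
unpaired bases (j - i >= 4).  Dot-bracket strings over ``( ) .`` are the
on-disk representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator

__all__ = [
    "CANONICAL_PAIRS",
    "MIN_HAIRPIN",
    "RnaSequence",
    "SecondaryStructure",
    "StructureError",
    "parse_dotbracket",
    "serialize_dotbracket",
    "base_pair_distance",
]

#: canonical Watson-Crick plus wobble pairs
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_HAIRPIN = 3


class StructureError(ValueError):
    """Raised for invalid sequences, structures or dot-bracket strings."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}.

    Input is normalised: lowercase is uppercased and T becomes U.
    """

    residues: str
    id: str = "seq"

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", norm)
        if len(norm) < 1:
            raise StructureError("sequence must have length >= 1")
        bad = set(norm) - set("ACGU")
        if bad:
            raise StructureError(f"non-ACGU residues: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """1-based residue access."""
        if not 1 <= i <= self.n:
            raise IndexError(i)
        return self.residues[i - 1]

    def can_pair(self, i: int, j: int) -> bool:
        """True if positions i < j may form a canonical pair with a legal hairpin."""
        return j - i >= MIN_HAIRPIN + 1 and (self[i], self[j]) in CANONICAL_PAIRS


def _check_pairs(pairs: frozenset[tuple[int, int]]) -> None:
    seen: set[int] = set()
    for i, j in pairs:
        if not (isinstance(i, int) and isinstance(j, int)):
            raise StructureError(f"pair positions must be integers: {(i, j)}")
        if not 1 <= i < j:
            raise StructureError(f"pair must satisfy 1 <= i < j: {(i, j)}")
        if j - i < MIN_HAIRPIN + 1:
            raise StructureError(f"hairpin too small for pair {(i, j)}")
        if i in seen or j in seen:
            raise StructureError(f"position paired twice near {(i, j)}")
        seen.add(i)
        seen.add(j)
    plist = sorted(pairs)
    for a in range(len(plist)):
        i, j = plist[a]
        for k, l in plist[a + 1:]:
            if k >= j:
                break
            if not (l < j):  # i < k < j, so require nesting k < l < j
                raise StructureError(f"crossing pairs {(i, j)} and {(k, l)}")


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs; the element s of the space Omega.

    ``n`` is the length of the underlying sequence, fixing the dot-bracket
    width and making structures on the same sequence directly comparable.
    """

    pairs: frozenset[tuple[int, int]]
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        if self.n < 1:
            raise StructureError("n must be >= 1")
        _check_pairs(self.pairs)
        for i, j in self.pairs:
            if j > self.n:
                raise StructureError(f"pair {(i, j)} out of range for n={self.n}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], n: int) -> "SecondaryStructure":
        return cls(frozenset((min(i, j), max(i, j)) for i, j in pairs), n)

    @classmethod
    def open_chain(cls, n: int) -> "SecondaryStructure":
        return cls(frozenset(), n)

    @cached_property
    def dotbracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @cached_property
    def pair_of(self) -> dict[int, int]:
        """Map each paired position to its partner."""
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.pairs))

    def validate_on(self, seq: RnaSequence) -> None:
        """Check length agreement and pair canonicity against ``seq``."""
        if seq.n != self.n:
            raise StructureError(f"structure length {self.n} != sequence length {seq.n}")
        for i, j in self.pairs:
            if (seq[i], seq[j]) not in CANONICAL_PAIRS:
                raise StructureError(
                    f"non-canonical pair {(i, j)}: {seq[i]}-{seq[j]}"
                )

    def stacked_adjacencies(self) -> int:
        """Number of pairs (i, j) with (i+1, j-1) also paired."""
        return sum(1 for i, j in self.pairs if (i + 1, j - 1) in self.pairs)

    # lexicographic order on dot-bracket strings ('(' < ')' < '.'), the
    # deterministic tie-break used throughout
    def __lt__(self, other: "SecondaryStructure") -> bool:
        return self.dotbracket < other.dotbracket


def parse_dotbracket(text: str, seq: RnaSequence | None = None) -> SecondaryStructure:
    """Parse a dot-bracket string by stack matching.

    If ``seq`` is given the length must match and every pair must be
    canonical on it.
    """
    bad = set(text) - set("().")
    if bad:
        raise StructureError(f"illegal dot-bracket characters: {sorted(bad)}")
    if seq is not None and len(text) != seq.n:
        raise StructureError(
            f"dot-bracket length {len(text)} != sequence length {seq.n}"
        )
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, c in enumerate(text, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    s = SecondaryStructure(frozenset(pairs), len(text))
    if seq is not None:
        s.validate_on(seq)
    return s


def serialize_dotbracket(s: SecondaryStructure, n: int | None = None) -> str:
    """Dot-bracket string of ``s``; round-trips with :func:`parse_dotbracket`."""
    if n is None or n == s.n:
        return s.dotbracket
    if any(j > n for _, j in s.pairs):
        raise StructureError(f"pair position exceeds n={n}")
    chars = ["."] * n
    for i, j in s.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def base_pair_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """d(s1, s2) = |s1| + |s2| - 2 |s1 n s2|.

    The minimum number of single base-pair insertions/removals transforming
    s1 into s2.
    """
    if s1.n != s2.n:
        raise StructureError("structures live on different sequence lengths")
    return len(s1.pairs) + len(s2.pairs) - 2 * len(s1.pairs & s2.pairs)
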