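"""IUPAC nucleotide alphabet utilities shared across the package.

Degenerate primers (N, R, Y, B, ...) are first-class citizens here: every
helper that touches a pattern works on the full 15-letter IUPAC DNA alphabet,
not just A/C/G/T.
"""
from __future__ import annotations

import itertools

import numpy as np

#: Expansion of each IUPAC nucleotide code into the set of concrete bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

DNA_BASES = "ACGT"
IUPAC_DNA = "".join(IUPAC_SETS)

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(_COMPLEMENT)

PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def validate_dna(seq: str, *, strict: bool = False, name: str = "sequence") -> None:
    """Raise ``ValueError`` if *seq* is empty or contains non-IUPAC characters.

    With ``strict=True`` only concrete A/C/G/T are accepted.
    """
    if not seq:
        raise ValueError(f"{name} is empty")
    allowed = set(DNA_BASES) if strict else set(IUPAC_DNA)
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"illegal character {ch!r} at position {pos} in {name}"
            )


def revcomp(seq: str) -> str:
    """Reverse complement, defined for every IUPAC code (N->N, Y->R, ...)."""
    return seq.translate(_COMP_TABLE)[::-1]


def expand(pattern: str) -> list[str]:
    """All concrete A/C/G/T strings a degenerate pattern stands for."""
    pools = [sorted(IUPAC_SETS[ch]) for ch in pattern]
    return ["".join(p) for p in itertools.product(*pools)]


def n_expansions(pattern: str) -> int:
    n = 1
    for ch in pattern:
        n *= len(IUPAC_SETS[ch])
    return n


def realize(pattern: str, rng: np.random.Generator) -> str:
    """Sample one concrete sequence compatible with a degenerate pattern.

    Each ambiguous position is resolved uniformly over its base set, so a
    perfect-match binding site for the pattern exists in the result.
    """
    out = []
    for ch in pattern:
        choices = sorted(IUPAC_SETS[ch])
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T string."""
    idx = rng.integers(0, 4, size=length)
    return "".join(DNA_BASES[i] for i in idx)


def bases_intersect(a: str, b: str) -> bool:
    """True when two IUPAC codes share at least one concrete base."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])
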