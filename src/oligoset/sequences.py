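"""Core DNA sequence primitives.

Sequences are plain Python ``str`` over the uppercase alphabet ``ACGT``
(5'->3'). "Complement" always means the *reverse* complement, i.e. the
antiparallel Watson-Crick partner strand: hybridization between two
subsequences requires one to equal the reverse complement of the other.
Coordinates are 0-based, half-open internally; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside A, C, G, T."""


def normalize(seq: str, *, name: str = "sequence") -> str:
    """Validate *seq* and return its canonical uppercase form.

    Lowercase input is accepted and uppercased. Any other character,
    including IUPAC ambiguity codes such as ``N``, is rejected: the design
    algorithm is defined only over the four unambiguous bases.
    """
    if not isinstance(seq, str):
        raise TypeError(f"{name} must be a string, got {type(seq).__name__}")
    s = seq.upper()
    if not s:
        raise AlphabetError(f"{name} is empty; length >= 1 required")
    for i, c in enumerate(s):
        if c not in ALPHABET:
            raise AlphabetError(
                f"{name} contains illegal character {c!r} at position {i + 1} "
                "(only A, C, G, T are allowed)"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Return the reverse complement (antiparallel partner strand) of *seq*."""
    return seq.translate(_COMPLEMENT)[::-1]


def windows(seq: str, k: int) -> list[str]:
    """All overlapping *k*-mers of *seq* in 5'->3' order.

    A sequence of length L has ``L - k + 1`` overlapping k-windows; these
    are the "critons" of the interstrand-uniqueness rules when ``k`` is the
    criton length.
    """
    n = len(seq)
    if k < 1:
        raise ValueError(f"window length must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"window length {k} exceeds sequence length {n}")
    return [seq[i : i + k] for i in range(n - k + 1)]


def is_palindrome(seq: str) -> bool:
    """True iff *seq* equals its own reverse complement.

    Such sequences are self-complementary (the loop-size-zero hairpin case)
    and necessarily have even length: in an odd-length sequence the middle
    base would have to pair with itself.
    """
    if len(seq) % 2:
        return False
    return seq == reverse_complement(seq)


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")
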