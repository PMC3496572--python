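"""Theoretical maximum set size under the criton rules.

Each accepted sequence of length L_s contains ``L_s - L_c + 1`` overlapping
criton windows, and consumes each window together with its reverse
complement (the anti-criton) from the supply of ``4**L_c`` words.
Self-complementary (palindromic) words are their own anti-critons and can
never be used, so for even L_c the ``4**(L_c/2)`` palindromic words are
subtracted from the supply; odd-length palindromic words do not exist.
Hence

    N_s = floor( (4**L_c - P) / (2 * (L_s - L_c + 1)) ),

with ``P = 4**(L_c/2)`` for even L_c and ``P = 0`` for odd L_c. This bound
holds in the global-criton-rules regime, where intrastrand limits prevent a
word from being reused within one strand; relaxing the intrastrand repeat
limit above L_c lets single strands reuse words and the bound no longer
applies.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CapacityResult:
    """Capacity bookkeeping for one (L_s, L_c) combination."""

    n_s: int
    num_critons: int
    num_palindromic_critons: int
    windows_per_sequence: int

    def as_dict(self) -> dict[str, int]:
        return {
            "max_set_size": self.n_s,
            "num_critons": self.num_critons,
            "num_palindromic_critons": self.num_palindromic_critons,
            "windows_per_sequence": self.windows_per_sequence,
        }


def max_set_size(seq_length: int, criton_length: int) -> CapacityResult:
    """Theoretical maximum number of length-``seq_length`` sequences.

    ``criton_length`` is the interstrand-uniqueness word length L_c.
    Integer arithmetic throughout; the quotient is floored (e.g.
    4032/30 = 134.4 -> 134 for L_s=20, L_c=6).
    """
    if criton_length < 1:
        raise ValueError("criton length must be >= 1")
    if criton_length > seq_length:
        raise ValueError(
            f"criton length {criton_length} exceeds sequence length {seq_length}"
        )
    num = 4**criton_length
    pal = 4 ** (criton_length // 2) if criton_length % 2 == 0 else 0
    wps = seq_length - criton_length + 1
    return CapacityResult(
        n_s=(num - pal) // (2 * wps),
        num_critons=num,
        num_palindromic_critons=pal,
        windows_per_sequence=wps,
    )


def yield_fraction(achieved: int, seq_length: int, criton_length: int) -> float:
    """Achieved set size as a fraction of the theoretical maximum."""
    if achieved < 0:
        raise ValueError("achieved set size must be >= 0")
    cap = max_set_size(seq_length, criton_length).n_s
    if cap == 0:
        raise ZeroDivisionError(
            f"capacity is zero for L_s={seq_length}, L_c={criton_length}; "
            "yield undefined"
        )
    return achieved / cap
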