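"""Nearest-neighbor free energy of DNA duplex formation.

Predicts the standard molar free enthalpy change dG°37 (kcal/mol, 37 °C,
1 M Na+) for a sequence paired with its full reverse complement:

    dG°37 = initiation + sum of stack terms + terminal corrections
            (+ symmetry correction if the strand is self-complementary)

where the stack terms run over the 5'->3' dinucleotide steps of the strand
and each stack equals that of its reverse complement (10 unique values
cover all 16 dinucleotides).

Two published parameter sets ship with the package:

* :data:`SANTALUCIA_1996` (default) — SantaLucia, Allawi & Seneviratne,
  Biochemistry 35:3555 (1996): initiation +1.82, symmetry +0.4, and a
  +0.4 kcal/mol penalty for each strand of the duplex with a thymine at
  its 5' end (the "fraying" penalty that motivates the GC-ends design
  option).
* :data:`UNIFIED_1998` — the unified oligonucleotide parameters
  (SantaLucia, PNAS 95:1460 (1998)): per-end initiation of +0.98 (G·C end)
  or +1.03 (A·T end), symmetry +0.43.

Only duplex formation with the perfect complement is modelled: hairpin
folding free energies, mismatches, dangling ends and salt corrections are
out of scope (the auditor reports structural stem/palindrome lengths
instead of hairpin energies).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

from .sequences import is_palindrome, normalize, reverse_complement

__all__ = ["NearestNeighborTable", "SANTALUCIA_1996", "UNIFIED_1998", "duplex_dg37"]


def _full_stacks(unique: dict[str, float]) -> MappingProxyType:
    """Expand the 10 unique stacks to all 16 via reverse-complement equality."""
    full = dict(unique)
    for step, dg in unique.items():
        full.setdefault(reverse_complement(step), dg)
    assert len(full) == 16
    return MappingProxyType(full)


@dataclass(frozen=True)
class NearestNeighborTable:
    """One published dG°37 parameter set (kcal/mol, 37 °C, 1 M Na+)."""

    name: str
    stack_dg37: MappingProxyType  # 5'->3' dinucleotide -> kcal/mol
    initiation_dg37: float  # per duplex
    terminal_at_penalty_dg37: float
    symmetry_correction_dg37: float
    # "five_prime_T": penalty per strand with 5'-terminal T (1996 set);
    # "per_AT_end":   penalty per terminal A·T base pair (unified set)
    terminal_penalty_mode: str = "five_prime_T"


SANTALUCIA_1996 = NearestNeighborTable(
    name="santalucia-1996",
    stack_dg37=_full_stacks(
        {
            "AA": -1.02,
            "AT": -0.73,
            "TA": -0.60,
            "CA": -1.38,
            "GT": -1.43,
            "CT": -1.16,
            "GA": -1.46,
            "CG": -2.09,
            "GC": -2.28,
            "GG": -1.77,
        }
    ),
    initiation_dg37=1.82,
    terminal_at_penalty_dg37=0.4,
    symmetry_correction_dg37=0.4,
    terminal_penalty_mode="five_prime_T",
)

UNIFIED_1998 = NearestNeighborTable(
    name="unified-1998",
    stack_dg37=_full_stacks(
        {
            "AA": -1.00,
            "AT": -0.88,
            "TA": -0.58,
            "CA": -1.45,
            "GT": -1.44,
            "CT": -1.28,
            "GA": -1.30,
            "CG": -2.17,
            "GC": -2.24,
            "GG": -1.84,
        }
    ),
    initiation_dg37=2 * 0.98,  # two G·C ends as the baseline
    terminal_at_penalty_dg37=1.03 - 0.98,  # per A·T end on top of it
    symmetry_correction_dg37=0.43,
    terminal_penalty_mode="per_AT_end",
)


def duplex_dg37(seq: str, table: NearestNeighborTable = SANTALUCIA_1996) -> float:
    """dG°37 (kcal/mol) of *seq* hybridized to its full reverse complement.

    More negative means a more stable duplex. Requires length >= 2 (a
    single base pair has no stack).
    """
    s = normalize(seq)
    if len(s) < 2:
        raise ValueError("duplex free energy requires a sequence of length >= 2")
    dg = table.initiation_dg37
    stacks = table.stack_dg37
    for i in range(len(s) - 1):
        dg += stacks[s[i : i + 2]]
    p = table.terminal_at_penalty_dg37
    if table.terminal_penalty_mode == "five_prime_T":
        # one penalty per strand whose 5' end is T: the strand itself, and
        # its complement (whose 5' end is T iff the strand ends in A)
        if s[0] == "T":
            dg += p
        if s[-1] == "A":
            dg += p
    else:  # per terminal A·T base pair
        if s[0] in "AT":
            dg += p
        if s[-1] in "AT":
            dg += p
    if is_palindrome(s):
        dg += table.symmetry_correction_dg37
    return dg
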