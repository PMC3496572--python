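"""Design constraints for sequence-set generation.

The nine user criteria of the design algorithm are collected in
:class:`DesignConstraints`:

* ``seq_length`` (L_s) and ``criton_length`` (L_c) — the sequence length
  and the interstrand-uniqueness word length. No L_c-base word, nor its
  reverse complement, may occur in more than one place across the whole set
  (including user-supplied *included* sequences).
* ``gc_min``/``gc_max`` — allowed G+C fraction (set both equal for an exact
  content). On lengths where an exact fraction is not an integer count, the
  pass band on counts is ``floor(gc_min * L_s) <= #GC <= ceil(gc_max * L_s)``.
* ``gc_ends`` — require G or C at both terminal positions (reduces end
  fraying of the duplex).
* ``forbidden_motifs`` — literal subsequences that may not occur (e.g.
  ``{GGG, CCC}`` against guanine tetrads). Complements are *not* added
  automatically; list both if both are unwanted.
* ``lsc`` — forbidden length of self-complementary (palindromic)
  subsequences, the loop-size-zero hairpin case.
* ``lhp`` — forbidden hairpin stem length (two reverse-complementary,
  non-overlapping arms within one strand).
* ``lsl`` — forbidden intrastrand repeat length ("sliding": a repeated
  subsequence lets a complementary strand hybridize at shifted registers).
* ``lni`` — forbidden length of words whose reverse complement occurs in
  the paired neighboring sequence (limits TAG-primer foldback).

Under the *global criton rules* regime used by older design tools the
intrastrand limits are slaved to the criton length:
``lsl = lhp = L_c`` and ``lsc = L_c`` (odd L_c) or ``L_c + 1`` (even L_c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .sequences import normalize

#: Value meaning "no limit" for lsc/lhp/lsl/lni (nothing is forbidden).
UNLIMITED = 0


def global_criton_rules(criton_length: int) -> dict[str, int]:
    """Intrastrand limits implied by the global criton rules for ``L_c``.

    Returns a dict with keys ``lsl``, ``lhp``, ``lsc`` suitable for
    :meth:`DesignConstraints.with_global_rules`.
    """
    if criton_length < 1:
        raise ValueError("criton length must be >= 1")
    lsc = criton_length if criton_length % 2 else criton_length + 1
    return {"lsl": criton_length, "lhp": criton_length, "lsc": lsc}


@dataclass(frozen=True)
class DesignConstraints:
    """All user criteria for one generation run. Immutable."""

    seq_length: int
    criton_length: int
    gc_min: float = 0.0
    gc_max: float = 1.0
    gc_ends: bool = False
    forbidden_motifs: tuple[str, ...] = ()
    included_sequences: tuple[str, ...] = ()
    neighbor_sequence: str | None = None
    lsc: int = UNLIMITED
    lhp: int = UNLIMITED
    lsl: int = UNLIMITED
    lni: int = UNLIMITED
    max_sequences: int | None = None
    complete: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if not 1 <= self.criton_length <= self.seq_length:
            raise ValueError(
                f"criton_length must satisfy 1 <= L_c <= L_s, got "
                f"L_c={self.criton_length}, L_s={self.seq_length}"
            )
        if not 0.0 <= self.gc_min <= self.gc_max <= 1.0:
            raise ValueError("GC bounds must satisfy 0 <= gc_min <= gc_max <= 1")
        for attr in ("lsc", "lhp", "lsl", "lni"):
            v = getattr(self, attr)
            if v != UNLIMITED and v < 2:
                raise ValueError(f"{attr} must be >= 2 (or 0 for no limit), got {v}")
        if self.max_sequences is not None and self.max_sequences < 1:
            raise ValueError("max_sequences must be >= 1")
        object.__setattr__(
            self, "forbidden_motifs",
            tuple(normalize(m, name="forbidden motif") for m in self.forbidden_motifs),
        )
        object.__setattr__(
            self, "included_sequences",
            tuple(normalize(s, name="included sequence") for s in self.included_sequences),
        )
        if self.neighbor_sequence is not None:
            object.__setattr__(
                self, "neighbor_sequence",
                normalize(self.neighbor_sequence, name="neighbor sequence"),
            )

    # -- derived quantities -------------------------------------------------

    @property
    def gc_count_bounds(self) -> tuple[int, int]:
        """Inclusive bounds on the G+C *count* of a full-length sequence."""
        lo = math.floor(self.gc_min * self.seq_length)
        hi = math.ceil(self.gc_max * self.seq_length)
        return lo, min(hi, self.seq_length)

    @property
    def remainder_length(self) -> int:
        """``L_s mod L_c`` — length of the terminal remainder block (0 if none)."""
        return self.seq_length % self.criton_length

    def with_global_rules(self) -> "DesignConstraints":
        """Copy of these constraints with lsl/lhp/lsc slaved to L_c."""
        return replace(self, **global_criton_rules(self.criton_length))

    def evolve(self, **changes) -> "DesignConstraints":
        return replace(self, **changes)


def global_constraints(
    seq_length: int, criton_length: int, **extra
) -> DesignConstraints:
    """Convenience constructor for the global-criton-rules regime."""
    rules = global_criton_rules(criton_length)
    rules.update(extra)
    return DesignConstraints(seq_length=seq_length, criton_length=criton_length, **rules)
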