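"""Independent set auditing and repeated-generation experiments.

The auditor re-measures every property of a finished set with the
standalone scans of :mod:`oligoset.properties` — none of the generator's
incremental machinery — so it can serve as an independent verification of
generated sets as well as of third-party sequence sets.

The experiment drivers regenerate sets many times under one configuration
and aggregate the set-size distribution (mean ± sample standard deviation,
extremes, mode, histogram), which is how set-design algorithms are
conventionally compared.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capacity import max_set_size
from .constraints import UNLIMITED, DesignConstraints
from .generator import generate_set
from .properties import (
    PropertyMeasurement,
    max_cross_hybridization,
    max_shared_word,
    measure,
)

__all__ = [
    "AuditReport",
    "ExperimentResult",
    "audit_set",
    "run_size_experiment",
    "sweep",
    "table1_grid",
    "Table1Grid",
]


@dataclass(frozen=True)
class AuditReport:
    """Full measurement report for a set of sequences.

    ``violations`` lists ``(sequence id, rule, measured value, threshold)``
    tuples; it is empty exactly when every measured maximum is strictly
    below its threshold. Sequence ids are 1-based positions in the input;
    included sequences are labelled ``included:<i>``.
    """

    sequence_ids: tuple[str, ...]
    per_sequence: tuple[PropertyMeasurement, ...]
    cross_matrix: np.ndarray  # pairwise max cross-hybridization (bases)
    shared_matrix: np.ndarray  # pairwise max same-orientation shared word
    max_interstrand_word: int
    max_internal_repeat: int
    max_palindrome: int
    max_hairpin_stem: int
    violations: tuple[tuple[str, str, int | float, int | float], ...]

    @property
    def clean(self) -> bool:
        return not self.violations

    def per_sequence_frame(self) -> pd.DataFrame:
        rows = []
        for sid, m in zip(self.sequence_ids, self.per_sequence):
            rows.append(
                {
                    "id": sid,
                    "gc_fraction": m.gc_fraction,
                    "gc_ends": m.has_gc_ends,
                    "max_palindrome": m.max_palindrome_len,
                    "max_hairpin_stem": m.max_hairpin_stem,
                    "max_internal_repeat": m.max_internal_repeat_len,
                    "motif_hits": len(m.forbidden_motif_hits),
                    "max_neighbor_complement": m.max_neighbor_complement_len,
                }
            )
        return pd.DataFrame(rows)


def _gc_bounds_for(length: int, c: DesignConstraints) -> tuple[int, int]:
    import math

    return math.floor(c.gc_min * length), min(math.ceil(c.gc_max * length), length)


def audit_set(
    sequences: list[str] | tuple[str, ...],
    constraints: DesignConstraints,
    included: list[str] | tuple[str, ...] = (),
    neighbors: list[str | None] | None = None,
) -> AuditReport:
    """Measure every property of *sequences* and list all rule violations.

    *included* sequences participate in the interstrand (criton
    uniqueness / cross-hybridization) checks but are not themselves
    audited. *neighbors*, if given, is aligned 1:1 with *sequences* (None
    entries allowed) and is checked with the ``lni`` foldback rule.
    Deterministic; independent of the generator.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("audit requires a non-empty set")
    if neighbors is not None and len(neighbors) != len(seqs):
        raise ValueError("neighbors must align 1:1 with sequences")
    c = constraints
    lc = c.criton_length
    ids = tuple(str(i + 1) for i in range(len(seqs)))
    violations: list[tuple[str, str, int | float, int | float]] = []

    per_seq = []
    for sid, s in zip(ids, seqs):
        nb = neighbors[int(sid) - 1] if neighbors else None
        m = measure(s, motifs=c.forbidden_motifs, neighbor=nb)
        per_seq.append(m)
        lo, hi = _gc_bounds_for(len(s), c)
        n_gc = round(m.gc_fraction * len(s))
        if not lo <= n_gc <= hi:
            violations.append((sid, "gc_content", n_gc, hi))
        if c.gc_ends and not m.has_gc_ends:
            violations.append((sid, "gc_ends", 0, 1))
        if m.forbidden_motif_hits:
            violations.append((sid, "motif", len(m.forbidden_motif_hits), 0))
        if c.lsc != UNLIMITED and m.max_palindrome_len >= c.lsc:
            violations.append((sid, "palindrome", m.max_palindrome_len, c.lsc))
        if c.lhp != UNLIMITED and m.max_hairpin_stem >= c.lhp:
            violations.append((sid, "hairpin", m.max_hairpin_stem, c.lhp))
        if c.lsl != UNLIMITED and m.max_internal_repeat_len >= c.lsl:
            violations.append((sid, "sliding", m.max_internal_repeat_len, c.lsl))
        if nb is not None and c.lni != UNLIMITED:
            if m.max_neighbor_complement_len >= c.lni:
                violations.append(
                    (sid, "neighbor", m.max_neighbor_complement_len, c.lni)
                )

    n = len(seqs)
    cross = np.zeros((n, n), dtype=int)
    shared = np.zeros((n, n), dtype=int)
    max_inter = 0
    for i in range(n):
        cross[i, i] = max_cross_hybridization(seqs[i], seqs[i])
        shared[i, i] = len(seqs[i])
        for j in range(i + 1, n):
            x = max_cross_hybridization(seqs[i], seqs[j])
            w = max_shared_word(seqs[i], seqs[j])
            cross[i, j] = cross[j, i] = x
            shared[i, j] = shared[j, i] = w
            max_inter = max(max_inter, x, w)
            if x >= lc:
                violations.append((f"{i + 1}~{j + 1}", "cross_hybridization", x, lc))
            if w >= lc:
                violations.append((f"{i + 1}~{j + 1}", "shared_word", w, lc))
    for k, inc in enumerate(included):
        for i in range(n):
            x = max_cross_hybridization(seqs[i], inc)
            w = max_shared_word(seqs[i], inc)
            max_inter = max(max_inter, x, w)
            if x >= lc:
                violations.append(
                    (f"{i + 1}~included:{k + 1}", "cross_hybridization", x, lc)
                )
            if w >= lc:
                violations.append((f"{i + 1}~included:{k + 1}", "shared_word", w, lc))

    return AuditReport(
        sequence_ids=ids,
        per_sequence=tuple(per_seq),
        cross_matrix=cross,
        shared_matrix=shared,
        max_interstrand_word=max_inter,
        max_internal_repeat=max(m.max_internal_repeat_len for m in per_seq),
        max_palindrome=max(m.max_palindrome_len for m in per_seq),
        max_hairpin_stem=max(m.max_hairpin_stem for m in per_seq),
        violations=tuple(violations),
    )


# ---------------------------------------------------------------------------
# repeated-generation experiments


@dataclass(frozen=True)
class ExperimentResult:
    """Set-size distribution over repeated generations of one configuration."""

    constraints: DesignConstraints
    n_runs: int
    seeds: tuple[int, ...]
    sizes: tuple[int, ...]
    all_complete: bool
    sd_defined: bool  # False for n_runs == 1 (sd reported as 0)

    @property
    def mean(self) -> float:
        return statistics.fmean(self.sizes)

    @property
    def sd(self) -> float:
        return statistics.stdev(self.sizes) if self.sd_defined else 0.0

    @property
    def min(self) -> int:
        return min(self.sizes)

    @property
    def max(self) -> int:
        return max(self.sizes)

    @property
    def mode(self) -> int:
        """Most frequent set size; ties broken toward the smaller size."""
        counts = Counter(self.sizes)
        best = max(counts.values())
        return min(s for s, c in counts.items() if c == best)

    @property
    def histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(self.sizes).items()))

    def summary(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "mode": self.mode,
            "histogram": self.histogram,
            "all_complete": self.all_complete,
        }


def _derive_seeds(seed: int | None, n_runs: int) -> tuple[int, ...]:
    base = 0 if seed is None else int(seed)
    return tuple((base + i) % (2**31) for i in range(n_runs))


def run_size_experiment(
    constraints: DesignConstraints,
    n_runs: int,
    seeds: list[int] | tuple[int, ...] | None = None,
    seed: int | None = None,
) -> ExperimentResult:
    """Generate *n_runs* sets with distinct seeds; aggregate the sizes.

    Pass explicit *seeds* (length ``n_runs``) or a master *seed* from which
    consecutive run seeds are derived. The statistics depend only on the
    multiset of run seeds.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = _derive_seeds(seed, n_runs)
    elif len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    sizes = []
    complete = True
    for s in seeds:
        result = generate_set(constraints, seed=s)
        sizes.append(len(result))
        complete = complete and result.complete
    return ExperimentResult(
        constraints=constraints,
        n_runs=n_runs,
        seeds=tuple(int(s) for s in seeds),
        sizes=tuple(sizes),
        all_complete=complete,
        sd_defined=n_runs > 1,
    )


_SWEEPABLE = {"gc_window", "lsl", "lhp"}


def sweep(
    parameter: str,
    values: list,
    base_config: DesignConstraints,
    n_runs: int,
    seed: int | None = None,
) -> list[ExperimentResult]:
    """One size experiment per value of *parameter* over a shared base.

    ``parameter`` is one of ``gc_window`` (values are ``(gc_min, gc_max)``
    pairs), ``lsl`` or ``lhp``. Every experiment uses the same run seeds,
    so differences between values are not seed artifacts.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {sorted(_SWEEPABLE)}")
    if not values:
        raise ValueError("values must be non-empty")
    results = []
    for v in values:
        if parameter == "gc_window":
            lo, hi = v
            cfg = base_config.evolve(gc_min=float(lo), gc_max=float(hi))
        else:
            cfg = base_config.evolve(**{parameter: int(v)})
        results.append(run_size_experiment(cfg, n_runs, seed=seed))
    return results


@dataclass(frozen=True)
class Table1Grid:
    """Mean set sizes and capacities over an (L_s, L_c) grid."""

    table: pd.DataFrame  # tidy: one row per (seq_length, criton_length)
    mean_yield: float  # average over cells of cell mean / capacity
    sd_yield: float  # spread of the per-cell yields (sample sd)

    def pivot(self, value: str = "mean") -> pd.DataFrame:
        return self.table.pivot(index="seq_length", columns="criton_length", values=value)


def table1_grid(
    seq_lengths,
    criton_lengths,
    n_runs: int,
    seed: int | None = None,
) -> Table1Grid:
    """Mean complete-set size per (L_s, L_c) cell, under global criton rules.

    Reports, per cell, the mean ± sd set size over *n_runs* generations
    alongside the theoretical capacity, and overall the average per-cell
    yield (mean size as a fraction of capacity).
    """
    from .constraints import global_constraints

    rows = []
    for lc in criton_lengths:
        for ls in seq_lengths:
            if lc > ls:
                continue
            cfg = global_constraints(ls, lc)
            res = run_size_experiment(cfg, n_runs, seed=seed)
            cap = max_set_size(ls, lc).n_s
            rows.append(
                {
                    "seq_length": ls,
                    "criton_length": lc,
                    "n_runs": n_runs,
                    "mean": res.mean,
                    "sd": res.sd,
                    "min": res.min,
                    "max": res.max,
                    "capacity": cap,
                    "yield": res.mean / cap if cap else float("nan"),
                }
            )
    table = pd.DataFrame(rows)
    yields = table["yield"].dropna()
    return Table1Grid(
        table=table,
        mean_yield=float(yields.mean()),
        sd_yield=float(yields.std(ddof=1)) if len(yields) > 1 else 0.0,
    )


def text_histogram(hist: dict[int, int], width: int = 50) -> str:
    """Plain-text bar rendering of a set-size histogram."""
    if not hist:
        return "(empty)"
    peak = max(hist.values())
    lines = []
    for size, count in sorted(hist.items()):
        bar = "#" * max(1, round(width * count / peak))
        lines.append(f"{size:6d} | {bar} {count}")
    return "\n".join(lines)
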