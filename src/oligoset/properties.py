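"""Per-sequence and sequence-vs-context property measurements.

Every rule of the design algorithm exists here twice over, in spirit: the
generator enforces the rules incrementally while a candidate grows, and the
functions in this module measure the same properties on finished sequences,
independently of the search, so that any emitted set can be audited. Each
measurement is a plain scan (no shared state with the generator).

All "complement" matching is reverse-complement (antiparallel) matching;
positions in returned hit lists are 1-based inclusive, per the package
convention for user-facing reports.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constraints import UNLIMITED, DesignConstraints
from .sequences import gc_count, reverse_complement, windows


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in *seq*."""
    return gc_count(seq) / len(seq)


def has_gc_ends(seq: str) -> bool:
    """True iff the first and last base are G or C."""
    return seq[0] in "GC" and seq[-1] in "GC"


def find_forbidden_motifs(
    seq: str, motifs: tuple[str, ...] | list[str]
) -> list[tuple[str, int]]:
    """All occurrences of any motif in *seq* as ``(motif, 1-based position)``.

    Overlapping occurrences are all reported. A motif longer than *seq*
    simply never hits. An empty result means the sequence passes.
    """
    hits: list[tuple[str, int]] = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append((motif, start + 1))
            start = seq.find(motif, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def _has_palindrome_of(seq: str, k: int) -> bool:
    """Any length-*k* window equal to its own reverse complement?"""
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(n - k + 1):
        # window seq[i:i+k]; its revcomp is rc[n-i-k : n-i]
        if seq[i : i + k] == rc[n - i - k : n - i]:
            return True
    return False


def max_palindrome_length(seq: str) -> int:
    """Length of the longest self-complementary (palindromic) subsequence.

    Palindromic subsequences have even length (the loop-size-zero hairpin
    case); returns 0 when none of length >= 2 exists. Monotone: every
    palindrome of length k >= 4 contains one of length k - 2 (trim one base
    from each end), so the maximum is found by stepping even lengths.
    """
    n = len(seq)
    best = 0
    k = 2
    while k <= n:
        if _has_palindrome_of(seq, k):
            best = k
            k += 2
        else:
            break
    return best


def _has_stem_of(seq: str, k: int, min_loop: int) -> bool:
    """Any two non-overlapping k-mer arms i < j, j >= i + k + min_loop,
    with window_j = revcomp(window_i)?"""
    n = len(seq)
    if 2 * k + min_loop > n:
        return False
    first: dict[str, int] = {}
    rc = reverse_complement(seq)
    for j in range(n - k + 1):
        w = seq[j : j + k]
        partner = first.get(rc[n - j - k : n - j])  # revcomp of w
        if partner is not None and partner <= j - k - min_loop:
            return True
        if w not in first:
            first[w] = j
    return False


def max_hairpin_stem(seq: str, min_loop: int = 0) -> int:
    """Longest hairpin stem (arm length, in bases) within one strand.

    A hairpin consists of two reverse-complementary arm subsequences (the
    stem) joined by a loop of ``>= min_loop`` unpaired bases; the arms must
    not overlap. With the default ``min_loop=0``, a palindrome of length 2k
    counts as a stem of length k, so forbidding stems of length L implies no
    palindromes of length >= 2L. Returns 0 when no stem of length >= 2
    exists (single-base-pair "stems" are not reported).
    """
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    n = len(seq)
    best = 0
    k = 2
    while 2 * k + min_loop <= n:
        if _has_stem_of(seq, k, min_loop):
            best = k
            k += 1
        else:
            break
    return best


def _has_repeat_of(seq: str, k: int) -> bool:
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if w in seen:
            return True
        seen.add(w)
    return False


def max_internal_repeat(seq: str) -> int:
    """Length of the longest subsequence occurring at >= 2 start positions.

    Overlapping occurrences count ("AAAA" has the 3-mer "AAA" twice). This
    is the "sliding" property: repeated subsequences let a complementary
    strand hybridize at shifted registers. Returns 0 if even the single
    bases are all distinct. Same-orientation repeats only; intrastrand
    reverse-complement matches are hairpin stems, not repeats.
    """
    lo, hi, best = 1, len(seq) - 1, 0
    while lo <= hi:  # binary search; repeated k-mers contain repeated (k-1)-mers
        mid = (lo + hi) // 2
        if _has_repeat_of(seq, mid):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def max_cross_hybridization(a: str, b: str) -> int:
    """Longest duplex (in base pairs) that *a* can form with *b*.

    The largest k such that some k-mer of *a* occurs reverse-complemented in
    *b*. Monotone in k, so found by binary search over shared k-mer sets.
    ``b`` may be another set member, an included sequence, a scaffold — or
    *a* itself, in which case palindromic words of *a* count (a strand can
    cross-hybridize with another copy of itself).
    """
    lo, hi, best = 1, min(len(a), len(b)), 0
    rc_b = reverse_complement(b)  # k-mer of rc(b) <=> revcomp of a k-mer of b
    while lo <= hi:
        mid = (lo + hi) // 2
        if _kmers(a, mid) & _kmers(rc_b, mid):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def max_shared_word(a: str, b: str) -> int:
    """Longest subsequence occurring in both *a* and *b* in the same
    orientation (the other half of criton uniqueness: a word used by two
    set members would hybridize both to the same anti-TAG)."""
    lo, hi, best = 1, min(len(a), len(b)), 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if _kmers(a, mid) & _kmers(b, mid):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def neighbor_conflict(tag: str, neighbor: str, lni: int) -> bool:
    """True iff *tag* contains a word of length >= *lni* whose reverse
    complement occurs in *neighbor* (foldback risk for a TAG tethered next
    to *neighbor*). Junction-spanning words of a direct concatenation are
    not considered; the check models a spacer between the two."""
    if lni < 2:
        raise ValueError("lni must be >= 2")
    return max_cross_hybridization(tag, neighbor) >= lni


@dataclass(frozen=True)
class PropertyMeasurement:
    """Measured intrastrand properties of one sequence."""

    gc_fraction: float
    has_gc_ends: bool
    max_palindrome_len: int
    max_hairpin_stem: int
    max_internal_repeat_len: int
    forbidden_motif_hits: tuple[tuple[str, int], ...]
    max_neighbor_complement_len: int = 0


def measure(
    seq: str,
    motifs: tuple[str, ...] = (),
    neighbor: str | None = None,
    min_loop: int = 0,
) -> PropertyMeasurement:
    """All intrastrand measurements for one sequence."""
    return PropertyMeasurement(
        gc_fraction=gc_content(seq),
        has_gc_ends=has_gc_ends(seq),
        max_palindrome_len=max_palindrome_length(seq),
        max_hairpin_stem=max_hairpin_stem(seq, min_loop),
        max_internal_repeat_len=max_internal_repeat(seq),
        forbidden_motif_hits=tuple(find_forbidden_motifs(seq, motifs)),
        max_neighbor_complement_len=(
            max_cross_hybridization(seq, neighbor) if neighbor is not None else 0
        ),
    )


@dataclass(frozen=True)
class CheckResult:
    """Outcome of :func:`check_sequence`: pass/fail plus the first reason."""

    ok: bool
    reason: str = ""
    rule: str = ""

    def __bool__(self) -> bool:  # truthiness == passed
        return self.ok


_PASS = CheckResult(True)


def context_criton_words(context: list[str] | tuple[str, ...], lc: int) -> set[str]:
    """All L_c windows of the context sequences plus their reverse
    complements — the words a new sequence may not contain."""
    banned: set[str] = set()
    for s in context:
        if len(s) < lc:
            continue
        for w in windows(s, lc):
            banned.add(w)
            banned.add(reverse_complement(w))
    return banned


def check_sequence(
    seq: str,
    constraints: DesignConstraints,
    context: list[str] | tuple[str, ...] = (),
) -> CheckResult:
    """Does *seq* satisfy every active criterion against *context*?

    *context* is the rest of the set plus any included sequences; the
    neighbor sequence (if any) is taken from the constraints. Checks run
    cheapest-first and the first failing rule is reported:
    length, GC ends, GC content, motifs, repeats, palindromes, stems,
    criton uniqueness, neighbor interaction.
    """
    c = constraints
    if len(seq) != c.seq_length:
        return CheckResult(False, f"length {len(seq)} != {c.seq_length}", "length")
    if c.gc_ends and not has_gc_ends(seq):
        return CheckResult(False, "terminal base not G/C", "gc_ends")
    lo, hi = c.gc_count_bounds
    n_gc = gc_count(seq)
    if not lo <= n_gc <= hi:
        return CheckResult(
            False, f"GC count {n_gc} outside [{lo}, {hi}]", "gc_content"
        )
    hits = find_forbidden_motifs(seq, c.forbidden_motifs)
    if hits:
        m, pos = hits[0]
        return CheckResult(False, f"forbidden motif {m} at position {pos}", "motif")
    if c.lsl != UNLIMITED:
        r = max_internal_repeat(seq)
        if r >= c.lsl:
            return CheckResult(False, f"internal repeat of length {r} >= {c.lsl}", "sliding")
    if c.lsc != UNLIMITED:
        p = max_palindrome_length(seq)
        if p >= c.lsc:
            return CheckResult(
                False, f"self-complementary subsequence of length {p} >= {c.lsc}",
                "palindrome",
            )
    if c.lhp != UNLIMITED:
        s = max_hairpin_stem(seq)
        if s >= c.lhp:
            return CheckResult(False, f"hairpin stem of length {s} >= {c.lhp}", "hairpin")
    banned = context_criton_words(context, c.criton_length)
    for i, w in enumerate(windows(seq, c.criton_length)):
        if w in banned:
            return CheckResult(
                False,
                f"criton {w} at position {i + 1} occurs in the set context "
                "(or its complement does)",
                "criton",
            )
    if c.neighbor_sequence is not None and c.lni != UNLIMITED:
        if neighbor_conflict(seq, c.neighbor_sequence, c.lni):
            k = max_cross_hybridization(seq, c.neighbor_sequence)
            return CheckResult(
                False, f"{k}-base complementarity with neighbor >= {c.lni}", "neighbor"
            )
    return _PASS
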