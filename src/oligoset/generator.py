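"""Exhaustive randomized backtracking generation of sequence sets.

The search assembles each candidate strand block-wise from "basic
sequences" (allowed criton-length words), left to right, in a random order;
a terminal remainder block of length ``L_s mod L_c`` finishes strands whose
length is not a multiple of the criton length. After every appended block
the whole growing string is re-validated, so junction-spanning windows are
screened like any others. Dead-end block prefixes are recorded as nogoods
and never re-entered; because every rule is monotone under extension
(a failing prefix cannot be rescued by more bases), and because the global
word constraints only tighten as sequences are accepted, nogoods remain
valid for the rest of one set's generation. A failed assembly is therefore
a proof that no further valid sequence exists — the set is *complete*.

Accepted sequences surrender all their criton windows and the reverse
complements of those windows: the words are physically removed from the
pool and banned from all later strings. Self-complementary words are never
used at all (each is its own anti-criton), which is what makes the
theoretical capacity of :mod:`oligoset.capacity` an attainable bound under
global criton rules.

Performance note: candidate blocks at each search node are prefiltered with
a vectorized necessary-condition mask (criton availability of every
junction-spanning window, GC feasibility, terminal-base demands) before the
exact incremental checker runs; the prefilter never rejects a block the
exact checker would accept, it only avoids Python-level work on the vast
majority of blocks that cannot extend the current prefix.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .constraints import UNLIMITED, DesignConstraints
from .properties import (
    context_criton_words,
    find_forbidden_motifs,
    max_hairpin_stem,
    max_internal_repeat,
    max_palindrome_length,
)
from .sequences import ALPHABET, gc_count, is_palindrome, reverse_complement, windows

logger = logging.getLogger(__name__)

__all__ = [
    "CritonPool",
    "NogoodStore",
    "SequenceSet",
    "OverConstrainedError",
    "enumerate_basic_sequences",
    "assemble_one",
    "record_nogood",
    "accept_sequence",
    "generate_set",
    "generate_paired_tags",
]


class OverConstrainedError(RuntimeError):
    """No basic sequence satisfies the constraints; nothing can be generated."""


# ---------------------------------------------------------------------------
# word encoding (A=0, C=1, G=2, T=3; first base most significant)

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# largest criton length for which the vectorized prefilter allocates its
# 4**L_c lookup tables (4**12 = 16 MiB of uint8)
_MAX_VECTOR_LC = 12

def _encode(word: str) -> int:
    v = 0
    for c in word:
        v = (v << 2) | _BASE_INDEX[c]
    return v


def _all_words(k: int) -> list[str]:
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


# ---------------------------------------------------------------------------
# pool and nogood store


@dataclass
class CritonPool:
    """The mutable supply of currently allowed basic sequences.

    ``allowed`` keeps enumeration order (stable, deterministic); removal is
    physical and append-only logged in ``forbidden_log`` as
    ``(word, reason)``.
    """

    criton_length: int
    remainder_length: int
    allowed: list[str]
    allowed_remainder: list[str]
    forbidden_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._allowed_set = set(self.allowed)

    def __len__(self) -> int:
        return len(self.allowed)

    def __contains__(self, word: str) -> bool:
        return word in self._allowed_set

    def remove(self, word: str, reason: str) -> bool:
        """Physically remove *word* if present; returns whether it was."""
        if word not in self._allowed_set:
            return False
        self._allowed_set.discard(word)
        self.allowed.remove(word)
        self.forbidden_log.append((word, reason))
        return True


@dataclass
class NogoodStore:
    """Dead block-choice prefixes. A stored prefix is never re-entered."""

    prefixes: set[tuple[str, ...]] = field(default_factory=set)

    def add(self, prefix: tuple[str, ...] | list[str]) -> None:
        self.prefixes.add(tuple(prefix))

    def __contains__(self, prefix: tuple[str, ...]) -> bool:
        return prefix in self.prefixes

    def __len__(self) -> int:
        return len(self.prefixes)


def record_nogood(prefix: list[str] | tuple[str, ...], nogoods: NogoodStore) -> NogoodStore:
    """Record a dead-ended block prefix (all suffix blocks were tried)."""
    nogoods.add(prefix)
    return nogoods


class _NullNogoods:
    """Disabled store (search correctness must not depend on nogoods)."""

    def add(self, prefix) -> None:
        pass

    def __contains__(self, prefix) -> bool:
        return False

    def __len__(self) -> int:
        return 0


@dataclass(frozen=True)
class SequenceSet:
    """An ordered, reproducible set of accepted sequences."""

    sequences: tuple[str, ...]
    constraints: DesignConstraints
    seed: int
    complete: bool
    runtime: float

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


# ---------------------------------------------------------------------------
# basic-sequence enumeration (the "filter" stage)


def _word_locally_ok(word: str, c: DesignConstraints, banned: set[str]) -> str | None:
    """Reason the word fails a locally-checkable criterion, or None."""
    if c.forbidden_motifs and find_forbidden_motifs(word, c.forbidden_motifs):
        return "forbidden motif"
    if c.lsl != UNLIMITED and max_internal_repeat(word) >= c.lsl:
        return "internal repeat"
    if c.lsc != UNLIMITED and max_palindrome_length(word) >= c.lsc:
        return "self-complementary"
    if c.lhp != UNLIMITED and max_hairpin_stem(word) >= c.lhp:
        return "hairpin stem"
    if banned and len(word) >= c.criton_length and word in banned:
        return "occurs in included/neighbor context"
    return None


def enumerate_basic_sequences(constraints: DesignConstraints) -> CritonPool:
    """All criton-length words obeying the locally-checkable criteria.

    Words containing a forbidden motif, an internal repeat of length >=
    lsl, a palindromic subsequence of length >= lsc, or a hairpin stem of
    length >= lhp, and words that occur (or whose reverse complement
    occurs) among the criton windows of included or neighbor sequences, are
    filtered out before the set generation starts. When the sequence length
    is not a multiple of the criton length, a remainder pool of
    ``L_s mod L_c``-length words is built the same way (remainder words are
    not critons and are only constrained through whole-string checks).
    """
    c = constraints
    context = list(c.included_sequences)
    if c.neighbor_sequence is not None:
        context.append(c.neighbor_sequence)
    banned = context_criton_words(context, c.criton_length)

    log: list[tuple[str, str]] = []
    allowed: list[str] = []
    for w in _all_words(c.criton_length):
        reason = _word_locally_ok(w, c, banned)
        if reason is None:
            allowed.append(w)
        else:
            log.append((w, reason))
    if not allowed:
        raise OverConstrainedError(
            f"no {c.criton_length}-base basic sequence satisfies the "
            "constraints; the design is over-constrained"
        )

    r = c.remainder_length
    allowed_r: list[str] = []
    if r:
        for w in _all_words(r):
            reason = _word_locally_ok(w, c, banned)
            if reason is None:
                allowed_r.append(w)
            else:
                log.append((w, f"remainder: {reason}"))
        if not allowed_r:
            raise OverConstrainedError(
                f"no {r}-base remainder block satisfies the constraints; "
                "the design is over-constrained"
            )
    return CritonPool(
        criton_length=c.criton_length,
        remainder_length=r,
        allowed=allowed,
        allowed_remainder=allowed_r,
        forbidden_log=log,
    )


def accept_sequence(seq: str, pool: CritonPool) -> CritonPool:
    """Remove every criton window of *seq* and its reverse complement.

    Removal is physical; duplicated windows (or a palindromic window, which
    equals its own complement) are removed once. The pool strictly shrinks
    on every acceptance of a sequence that was assembled from it.
    """
    lc = pool.criton_length
    for w in dict.fromkeys(windows(seq, lc)):  # preserve order, dedupe
        pool.remove(w, "used")
        pool.remove(reverse_complement(w), "complement of used word")
    return pool


# ---------------------------------------------------------------------------
# incremental whole-string checker


class IncrementalChecker:
    """Validates a growing string one appended block at a time.

    Every design rule is monotone under extension, so it suffices to check
    only the windows the new characters create. ``push`` either commits the
    block (returning True) or leaves the state untouched (False); ``pop``
    undoes the last committed block.
    """

    def __init__(self, constraints: DesignConstraints, forbidden_words: set[str]):
        c = constraints
        self.ls = c.seq_length
        self.lc = c.criton_length
        self.gc_lo, self.gc_hi = c.gc_count_bounds
        self.gc_ends = c.gc_ends
        self.motifs = c.forbidden_motifs
        self.forbidden = forbidden_words
        self.k_rep = c.lsl if c.lsl != UNLIMITED else 0
        self.k_hp = c.lhp if c.lhp != UNLIMITED else 0
        self.p_pal = 0 if c.lsc == UNLIMITED else c.lsc + (c.lsc % 2)
        self.k_ni = c.lni if c.lni != UNLIMITED else 0
        self.neighbor_rc: set[str] = set()
        if c.neighbor_sequence is not None and self.k_ni:
            n, k = c.neighbor_sequence, self.k_ni
            if len(n) >= k:
                self.neighbor_rc = {
                    reverse_complement(n[i : i + k]) for i in range(len(n) - k + 1)
                }
        self.s = ""
        self.gc = 0
        self._rep_first: dict[str, int] = {}
        self._hp_first: dict[str, int] = {}
        self._frames: list[tuple[int, int, list[str], list[str]]] = []

    def push(self, block: str) -> bool:
        s0 = self.s
        n0 = len(s0)
        new = s0 + block
        n1 = len(new)
        g = self.gc + gc_count(block)
        if g > self.gc_hi or g + (self.ls - n1) < self.gc_lo:
            return False
        if self.gc_ends:
            if n0 == 0 and new[0] not in "GC":
                return False
            if n1 == self.ls and new[-1] not in "GC":
                return False
        for m in self.motifs:
            if new.find(m, max(0, n0 - len(m) + 1)) != -1:
                return False
        lc = self.lc
        if n1 >= lc:
            forbidden = self.forbidden
            for j in range(max(0, n0 - lc + 1), n1 - lc + 1):
                w = new[j : j + lc]
                if w in forbidden or w == reverse_complement(w):
                    return False
        p = self.p_pal
        if p and n1 >= p:
            for j in range(max(0, n0 - p + 1), n1 - p + 1):
                w = new[j : j + p]
                if w == reverse_complement(w):
                    return False
        k = self.k_ni
        if self.neighbor_rc and n1 >= k:
            rc_set = self.neighbor_rc
            for j in range(max(0, n0 - k + 1), n1 - k + 1):
                if new[j : j + k] in rc_set:
                    return False
        # repeats and stems insert into first-occurrence maps as they scan,
        # so collisions *within* the new block are caught too; inserts are
        # journaled and rolled back on failure
        rep_added: list[str] = []
        hp_added: list[str] = []
        ok = True
        k = self.k_rep
        if k and n1 >= k:
            d = self._rep_first
            for j in range(max(0, n0 - k + 1), n1 - k + 1):
                w = new[j : j + k]
                if w in d:
                    ok = False
                    break
                d[w] = j
                rep_added.append(w)
        k = self.k_hp
        if ok and k and n1 >= k:
            d = self._hp_first
            for j in range(max(0, n0 - k + 1), n1 - k + 1):
                w = new[j : j + k]
                i = d.get(reverse_complement(w))
                if i is not None and i <= j - k:  # non-overlapping arms
                    ok = False
                    break
                if w not in d:
                    d[w] = j
                    hp_added.append(w)
        if not ok:
            for w in rep_added:
                del self._rep_first[w]
            for w in hp_added:
                del self._hp_first[w]
            return False
        self._frames.append((n0, self.gc, rep_added, hp_added))
        self.s = new
        self.gc = g
        return True

    def pop(self) -> None:
        n0, gc, rep_added, hp_added = self._frames.pop()
        for w in rep_added:
            del self._rep_first[w]
        for w in hp_added:
            del self._hp_first[w]
        self.s = self.s[:n0]
        self.gc = gc


# ---------------------------------------------------------------------------
# the assembler (one set's search state)


class _Assembler:
    def __init__(
        self,
        constraints: DesignConstraints,
        pool: CritonPool,
        forbidden: set[str],
        nogoods,
        rng: np.random.Generator,
    ):
        c = constraints
        self.c = c
        self.pool = pool
        self.forbidden = forbidden
        self.nogoods = nogoods
        self.rng = rng
        self.lc = c.criton_length
        self.ls = c.seq_length
        self.r = c.remainder_length
        self.nb_full = c.seq_length // c.criton_length
        self.gc_lo, self.gc_hi = c.gc_count_bounds
        # prefilter bans a pool word once it has appeared as a window of the
        # growing string; that is a necessary rejection only when a repeated
        # criton implies a repeated lsl-subsequence
        self.ban_seen = c.lsl != UNLIMITED and c.lsl <= c.criton_length
        self.vector = c.criton_length <= _MAX_VECTOR_LC
        if self.vector:
            size = 4**c.criton_length
            self.available = np.ones(size, dtype=np.uint8)
            for w in forbidden:
                self.available[_encode(w)] = 0
            if c.criton_length % 2 == 0:
                for w in _all_words(c.criton_length // 2):
                    self.available[_encode(w + reverse_complement(w))] = 0
            self._pow4 = [4**t for t in range(c.criton_length + 1)]

    # -- bookkeeping between assemblies -------------------------------------

    def ban_word(self, word: str) -> None:
        """Permanently ban *word* (it was consumed by an accepted sequence)."""
        self.forbidden.add(word)
        if self.vector:
            self.available[_encode(word)] = 0

    # -- one assembly (one "trail") -----------------------------------------

    def assemble(self) -> str | None:
        """Search for one full-length sequence, or prove none exists.

        The pool is shuffled once per assembly; the depth-first search then
        combines blocks systematically in that order, pruning recorded
        nogood prefixes, so randomness only permutes exploration order and
        a failed search is a proof that no assembly from the current pool
        succeeds.
        """
        usable = [w for w in self.pool.allowed if not is_palindrome(w)]
        if not usable:
            return None
        perm = self.rng.permutation(len(usable))
        self.words = [usable[i] for i in perm]
        r_words = list(self.pool.allowed_remainder) if self.r else []
        if r_words:
            perm_r = self.rng.permutation(len(r_words))
            r_words = [r_words[i] for i in perm_r]
        self.r_words = r_words
        if self.vector:
            n = len(self.words)
            self.W = np.fromiter((_encode(w) for w in self.words), np.int64, n)
            self.GCW = np.fromiter((gc_count(w) for w in self.words), np.int64, n)
            self.FIRSTGC = np.fromiter(((w[0] in "GC") for w in self.words), bool, n)
            self.LASTGC = np.fromiter(((w[-1] in "GC") for w in self.words), bool, n)
            self.ok = self.available.copy()
        checker = IncrementalChecker(self.c, self.forbidden)
        return self._search(0, checker, [])

    def _candidates(self, checker: IncrementalChecker):
        """Indices of blocks passing the vectorized necessary conditions."""
        n = len(checker.s)
        lc = self.lc
        if not self.vector:
            return range(len(self.words))
        ok = self.ok
        valid = ok[self.W] != 0
        rem_after = self.ls - (n + lc)
        hi = self.gc_hi - checker.gc
        lo = self.gc_lo - checker.gc - rem_after
        valid &= self.GCW <= hi
        if lo > 0:
            valid &= self.GCW >= lo
        if self.c.gc_ends:
            if n == 0:
                valid &= self.FIRSTGC
            if rem_after == 0 and self.r == 0:
                valid &= self.LASTGC
        if n > 0:
            p4 = self._pow4
            s_tail = _encode(checker.s[-(lc - 1) :]) if lc > 1 else 0
            shifted = self.W
            for t in range(1, lc):
                shifted = shifted >> 2
                win = (s_tail % p4[t]) * p4[lc - t] + shifted
                valid &= ok[win] != 0
        return np.flatnonzero(valid)

    def _ban_new_windows(self, checker: IncrementalChecker) -> list[tuple[int, int]]:
        """Prefilter bans for the windows the last push created."""
        if not (self.vector and self.ban_seen):
            return []
        lc = self.lc
        s = checker.s
        n1 = len(s)
        n0 = n1 - lc
        journal: list[tuple[int, int]] = []
        ok = self.ok
        for j in range(max(0, n0 - lc + 1), n1 - lc + 1):
            idx = _encode(s[j : j + lc])
            journal.append((idx, int(ok[idx])))
            ok[idx] = 0
        return journal

    def _search(self, depth: int, checker: IncrementalChecker, path: list[str]):
        """Systematic depth-first search in this assembly's block order.

        Dead block prefixes are recorded as nogoods ("forbidden to occur at
        the beginning of a string") and pruned in later assemblies of the
        same set; the next trail in effect skips the blocks leading to
        them. Records at every dead node, so a failed search at the root is
        an exhaustion proof.
        """
        if len(checker.s) == self.ls:
            return checker.s
        nogoods = self.nogoods
        if depth == self.nb_full:  # terminal remainder block
            for rw in self.r_words:
                if checker.push(rw):
                    return checker.s
            nogoods.add(tuple(path))
            return None
        words = self.words
        for i in self._candidates(checker):
            w = words[i]
            path.append(w)
            if tuple(path) in nogoods:
                path.pop()
                continue
            if checker.push(w):
                journal = self._ban_new_windows(checker)
                res = self._search(depth + 1, checker, path)
                if res is not None:
                    return res
                for idx, old in reversed(journal):
                    self.ok[idx] = old
                checker.pop()
            path.pop()
        nogoods.add(tuple(path))
        return None


def assemble_one(
    pool: CritonPool,
    constraints: DesignConstraints,
    nogoods: NogoodStore,
    rng: np.random.Generator,
    forbidden_words: set[str] | None = None,
) -> str | None:
    """Assemble one full-length sequence from *pool*, or prove none exists.

    *forbidden_words* are the criton words already consumed by the set
    context (accepted members, included and neighbor sequences, plus their
    reverse complements); defaults to the included/neighbor context of the
    constraints.
    """
    if forbidden_words is None:
        context = list(constraints.included_sequences)
        if constraints.neighbor_sequence is not None:
            context.append(constraints.neighbor_sequence)
        forbidden_words = context_criton_words(context, constraints.criton_length)
    asm = _Assembler(constraints, pool, forbidden_words, nogoods, rng)
    return asm.assemble()


# ---------------------------------------------------------------------------
# set generation


def _resolve_seed(constraints: DesignConstraints, seed: int | None) -> int:
    if seed is not None:
        return int(seed)
    if constraints.seed is not None:
        return int(constraints.seed)
    return int(np.random.SeedSequence().entropy % (2**31))


def generate_set(
    constraints: DesignConstraints,
    seed: int | None = None,
    *,
    use_nogoods: bool = True,
) -> SequenceSet:
    """Generate a maximum set of sequences under *constraints*.

    Repeats assemble/accept until ``max_sequences`` is reached or an
    assembly proves that no further valid sequence exists (in which case
    the returned set is flagged *complete* — exhaustion proved). The result
    is a pure function of ``(constraints, seed)``.

    Raises :class:`OverConstrainedError` if no basic sequence exists at
    all; once generation has started, running out of options is not an
    error but the normal completion of the set.
    """
    t0 = time.perf_counter()
    actual_seed = _resolve_seed(constraints, seed)
    rng = np.random.default_rng(actual_seed)
    pool = enumerate_basic_sequences(constraints)
    context = list(constraints.included_sequences)
    if constraints.neighbor_sequence is not None:
        context.append(constraints.neighbor_sequence)
    forbidden = context_criton_words(context, constraints.criton_length)
    nogoods = NogoodStore() if use_nogoods else _NullNogoods()
    asm = _Assembler(constraints, pool, forbidden, nogoods, rng)

    sequences: list[str] = []
    complete = False
    while True:
        if (
            constraints.max_sequences is not None
            and len(sequences) >= constraints.max_sequences
        ):
            break
        seq = asm.assemble()
        if seq is None:
            complete = True
            break
        sequences.append(seq)
        logger.info("accepted sequence %d: %s", len(sequences), seq)
        accept_sequence(seq, pool)
        for w in dict.fromkeys(windows(seq, constraints.criton_length)):
            asm.ban_word(w)
            asm.ban_word(reverse_complement(w))
    logger.info(
        "generation finished: %d sequences, complete=%s, %d basic sequences "
        "left in the pool, %d nogood prefixes recorded",
        len(sequences), complete, len(pool), len(nogoods),
    )
    return SequenceSet(
        sequences=tuple(sequences),
        constraints=constraints,
        seed=actual_seed,
        complete=complete,
        runtime=time.perf_counter() - t0,
    )


def generate_paired_tags(
    constraints: DesignConstraints,
    neighbors: list[str],
    seed: int | None = None,
) -> SequenceSet:
    """Generate one TAG per neighbor sequence, pairing them 1:1.

    The criton windows of *all* neighbors (and of every previously accepted
    TAG) are globally forbidden; the foldback rule ``lni`` is applied to
    each TAG only against its own neighbor. ``constraints.lni`` must be set.
    """
    if constraints.lni == UNLIMITED:
        raise ValueError("generate_paired_tags requires lni to be set")
    t0 = time.perf_counter()
    actual_seed = _resolve_seed(constraints, seed)
    tags: list[str] = []
    for i, neighbor in enumerate(neighbors):
        c_i = constraints.evolve(
            neighbor_sequence=neighbor,
            max_sequences=1,
            included_sequences=tuple(constraints.included_sequences)
            + tuple(neighbors[:i])
            + tuple(neighbors[i + 1 :])
            + tuple(tags),
            seed=None,
        )
        result = generate_set(c_i, seed=(actual_seed + i) % (2**31))
        if not result.sequences:
            raise OverConstrainedError(
                f"no TAG could be generated for neighbor {i + 1} of "
                f"{len(neighbors)}; {len(tags)} TAGs were designed before "
                "the failure"
            )
        tags.append(result.sequences[0])
    return SequenceSet(
        sequences=tuple(tags),
        constraints=constraints,
        seed=actual_seed,
        complete=False,
        runtime=time.perf_counter() - t0,
    )
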