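"""Property measurements against independent brute-force oracles.

The oracles below enumerate all substring (pairs) explicitly — O(n^2)/O(n^3)
— and share no code with the binary-search/first-occurrence implementations
they validate.
"""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oligoset import (
    DesignConstraints,
    check_sequence,
    find_forbidden_motifs,
    gc_content,
    has_gc_ends,
    max_cross_hybridization,
    max_hairpin_stem,
    max_internal_repeat,
    max_palindrome_length,
    max_shared_word,
    neighbor_conflict,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)
dna_pairs = st.tuples(
    st.text(alphabet="ACGT", min_size=1, max_size=30),
    st.text(alphabet="ACGT", min_size=1, max_size=30),
)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_max_palindrome(s):
    best = 0
    for i in range(len(s)):
        for j in range(i + 2, len(s) + 1):
            sub = s[i:j]
            if sub == reverse_complement(sub):
                best = max(best, len(sub))
    return best


def brute_max_stem(s, min_loop=0):
    best = 0
    n = len(s)
    for k in range(2, n + 1):
        for i in range(n - k + 1):
            for j in range(i + k + min_loop, n - k + 1):
                if s[j : j + k] == reverse_complement(s[i : i + k]):
                    best = max(best, k)
    return best


def brute_max_repeat(s):
    best = 0
    for k in range(1, len(s)):
        seen = set()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if w in seen:
                best = max(best, k)
                break
            seen.add(w)
    return best


def brute_max_cross(a, b):
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for i in range(len(a) - k + 1):
            if reverse_complement(a[i : i + k]) in b:
                best = max(best, k)
                break
    return best


def brute_max_shared(a, b):
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for i in range(len(a) - k + 1):
            if a[i : i + k] in b:
                best = max(best, k)
                break
    return best


# ---------------------------------------------------------------------------
# simple measurements


def test_gc_content_and_ends():
    assert gc_content("GGCC") == 1.0
    assert gc_content("ATAT") == 0.0
    assert gc_content("GCAT") == 0.5
    assert has_gc_ends("GAAAC")
    assert not has_gc_ends("TAAAC")
    assert not has_gc_ends("GAAAT")


def test_find_forbidden_motifs():
    assert find_forbidden_motifs("AGGGA", ("GGG", "CCC")) == [("GGG", 2)]
    assert find_forbidden_motifs("AAAAA", ("AAAAA",)) == [("AAAAA", 1)]
    assert find_forbidden_motifs("ACGT", ("GGG", "CCC")) == []
    assert find_forbidden_motifs("AC", ("ACGTACGT",)) == []  # motif longer: no hit
    # overlapping occurrences are all reported
    assert find_forbidden_motifs("GGGG", ("GGG",)) == [("GGG", 1), ("GGG", 2)]


def test_max_palindrome_examples():
    assert max_palindrome_length("AAGAATTCAA") == 6  # GAATTC
    assert max_palindrome_length("AAAAA") == 0
    assert max_palindrome_length("AT") == 2
    assert max_palindrome_length("ACGT") == 4


def test_max_hairpin_stem_examples():
    s = "CAAGGTCTGCTTGATTTGGAGG"  # published sequence with arms CAAG / CTTG
    assert max_hairpin_stem(s) == 4
    assert max_hairpin_stem("ACGT") == 2  # palindrome = loop-0 hairpin
    assert max_hairpin_stem("AAAAAAAA") == 0
    assert max_hairpin_stem("ACGT", min_loop=1) == 0


def test_max_internal_repeat_examples():
    assert max_internal_repeat("ACGTACGT") == 4
    assert max_internal_repeat("AAAA") == 3  # overlapping occurrences count
    assert max_internal_repeat("ACGT") == 0
    assert max_internal_repeat("A") == 0


def test_max_cross_hybridization_examples():
    assert max_cross_hybridization("AAAA", "TTTT") == 4
    assert max_cross_hybridization("ACGT", "ACGT") == 4  # self-palindromic
    assert max_cross_hybridization("AAAA", "AAAA") == 0


@given(dna)
def test_palindrome_matches_bruteforce(s):
    assert max_palindrome_length(s) == brute_max_palindrome(s)


@given(dna, st.integers(min_value=0, max_value=3))
def test_stem_matches_bruteforce(s, min_loop):
    assert max_hairpin_stem(s, min_loop) == brute_max_stem(s, min_loop)


@given(dna)
def test_repeat_matches_bruteforce(s):
    assert max_internal_repeat(s) == brute_max_repeat(s)


@given(dna_pairs)
def test_cross_hybridization_matches_bruteforce(pair):
    a, b = pair
    assert max_cross_hybridization(a, b) == brute_max_cross(a, b)
    assert max_shared_word(a, b) == brute_max_shared(a, b)


@given(dna)
def test_palindrome_is_even_and_loop0_stem_consistent(s):
    p = max_palindrome_length(s)
    assert p % 2 == 0
    # a length-2k palindrome is a loop-0 stem of length k (stems below the
    # reporting floor of 2 — i.e. length-2 palindromes — excepted)
    if p >= 4:
        assert max_hairpin_stem(s, min_loop=0) >= p // 2


def test_neighbor_conflict():
    # tag contains the reverse complement of a 3-mer of the neighbor
    assert neighbor_conflict("TTAGC", "AGCTA", 3)  # GCT ~ AGC
    assert not neighbor_conflict("AAAAA", "AAAAA", 3)  # poly-A vs poly-A
    with pytest.raises(ValueError):
        neighbor_conflict("ACGT", "ACGT", 1)


# ---------------------------------------------------------------------------
# the combined pass/fail check


def _constraints(**kw):
    base = dict(seq_length=10, criton_length=4, lsc=4, lhp=3, lsl=4)
    base.update(kw)
    return DesignConstraints(**base)


def test_check_sequence_first_failure_reported():
    c = _constraints(gc_ends=True)
    assert check_sequence("GACTTACAGC", c)
    assert check_sequence("AACTTACAGC", c).rule == "gc_ends"
    c2 = _constraints(forbidden_motifs=("GGG",))
    assert check_sequence("AGGGTACATC", c2).rule == "motif"


def test_check_sequence_criton_uniqueness_against_context():
    c = _constraints()
    seq = "GACTTACAGC"
    assert check_sequence(seq, c, context=[seq]).rule == "criton"  # shares all words
    # reverse complement windows are forbidden too
    assert check_sequence(seq, c, context=[reverse_complement(seq)]).rule == "criton"
    other = "TGGATGTGAC"
    assert check_sequence(seq, c, context=[]).ok


def test_check_sequence_detects_published_stem():
    c = DesignConstraints(seq_length=22, criton_length=5, lhp=4, lsc=6, lsl=6)
    res = check_sequence("CAAGGTCTGCTTGATTTGGAGG", c)
    assert not res.ok and res.rule == "hairpin"


@given(dna, dna)
def test_intrastrand_failures_are_monotone_under_extension(s, suffix):
    """A prefix failing a motif/palindrome/stem/repeat rule still fails after
    extension — the property that justifies incremental pruning."""
    c = DesignConstraints(
        seq_length=len(s), criton_length=min(4, len(s)), lsc=4, lhp=2, lsl=3,
        forbidden_motifs=("GGG",),
    )
    res = check_sequence(s, c)
    if res.ok or res.rule in ("length", "gc_content", "gc_ends", "criton"):
        return
    extended = s + suffix
    c2 = c.evolve(seq_length=len(extended))
    res2 = check_sequence(extended, c2)
    assert not res2.ok
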