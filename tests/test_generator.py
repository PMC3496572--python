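"""Pool enumeration, assembly, nogood learning and set generation."""

import numpy as np
import pytest

from oligoset import (
    DesignConstraints,
    NogoodStore,
    OverConstrainedError,
    accept_sequence,
    assemble_one,
    check_sequence,
    enumerate_basic_sequences,
    generate_paired_tags,
    generate_set,
    global_constraints,
    global_criton_rules,
    is_palindrome,
    max_cross_hybridization,
    max_set_size,
    record_nogood,
    reverse_complement,
    windows,
)
from oligoset.generator import CritonPool


def test_global_criton_rules_parity():
    assert global_criton_rules(5) == {"lsl": 5, "lhp": 5, "lsc": 5}
    assert global_criton_rules(6) == {"lsl": 6, "lhp": 6, "lsc": 7}


# ---------------------------------------------------------------------------
# enumeration (the filter stage)


def test_enumerate_pool_sizes():
    c = DesignConstraints(seq_length=8, criton_length=2)
    assert len(enumerate_basic_sequences(c)) == 16  # no constraints
    c = DesignConstraints(seq_length=9, criton_length=3, forbidden_motifs=("GGG", "CCC"))
    assert len(enumerate_basic_sequences(c)) == 62  # 64 - 2
    c = DesignConstraints(seq_length=8, criton_length=4, lsc=4)
    assert len(enumerate_basic_sequences(c)) == 240  # 256 - 16 palindromic 4-mers


def test_enumerate_builds_remainder_pool():
    c = DesignConstraints(seq_length=10, criton_length=4, forbidden_motifs=("AA",))
    pool = enumerate_basic_sequences(c)
    assert pool.remainder_length == 2
    assert "AA" not in pool.allowed_remainder
    assert len(pool.allowed_remainder) == 15


def test_enumerate_respects_included_context():
    inc = "ACGTACGTAC"
    c = DesignConstraints(seq_length=8, criton_length=4, included_sequences=(inc,))
    pool = enumerate_basic_sequences(c)
    for w in windows(inc, 4):
        assert w not in pool
        assert reverse_complement(w) not in pool


def test_enumerate_over_constrained():
    c = DesignConstraints(
        seq_length=4, criton_length=2, forbidden_motifs=("A", "C", "G", "T")
    )
    with pytest.raises(OverConstrainedError):
        enumerate_basic_sequences(c)


# ---------------------------------------------------------------------------
# acceptance bookkeeping


def test_accept_sequence_removes_windows_and_complements():
    c = DesignConstraints(seq_length=10, criton_length=4)
    pool = enumerate_basic_sequences(c)
    n0 = len(pool)
    # contains a palindromic window (ACGT) and a repeated window pair
    accept_sequence("ACGTACGTAA", pool)
    removed = {w for w, _ in pool.forbidden_log}
    assert removed == {"ACGT", "CGTA", "TACG", "GTAC", "GTAA", "TTAC"}
    assert len(pool) == n0 - 6  # palindromic/duplicated windows removed once
    assert n0 - len(pool) <= 14  # at most 7 windows + complements


def test_accept_strictly_shrinks_pool():
    c = global_constraints(10, 4)
    result = generate_set(c, seed=3)
    pool = enumerate_basic_sequences(c)
    sizes = [len(pool)]
    for s in result.sequences:
        accept_sequence(s, pool)
        sizes.append(len(pool))
    assert all(b < a for a, b in zip(sizes, sizes[1:]))


# ---------------------------------------------------------------------------
# assembly


def test_assemble_block_structure_with_remainder():
    c = global_constraints(10, 4)
    pool = enumerate_basic_sequences(c)
    seq = assemble_one(pool, c, NogoodStore(), np.random.default_rng(0))
    assert seq is not None and len(seq) == 10
    assert seq[8:] in pool.allowed_remainder  # 4 + 4 + 2 block structure
    assert check_sequence(seq, c).ok


def test_assemble_exhausted_on_degenerate_pool():
    c = DesignConstraints(seq_length=4, criton_length=2, lsl=2)
    pool = CritonPool(criton_length=2, remainder_length=0, allowed=["AA"],
                      allowed_remainder=[])
    assert assemble_one(pool, c, NogoodStore(), np.random.default_rng(0)) is None


def test_assemble_is_deterministic_for_a_seed():
    c = global_constraints(12, 4)
    out = [
        assemble_one(enumerate_basic_sequences(c), c, NogoodStore(),
                     np.random.default_rng(42))
        for _ in range(2)
    ]
    assert out[0] == out[1]


def test_record_nogood_prunes_prefix():
    store = NogoodStore()
    record_nogood(["ACGG", "TTAC"], store)
    assert ("ACGG", "TTAC") in store
    assert ("ACGG",) not in store
    assert len(store) == 1


def test_nogood_store_does_not_change_set_sizes():
    # equivalence oracle on small instances: nogoods are pure pruning
    c = global_constraints(6, 2)
    for seed in range(5):
        with_ng = generate_set(c, seed=seed, use_nogoods=True)
        without = generate_set(c, seed=seed, use_nogoods=False)
        assert with_ng.complete and without.complete
        assert len(with_ng) == len(without)


# ---------------------------------------------------------------------------
# whole-set generation


def test_generate_set_seeded_determinism():
    c = global_constraints(12, 4, seed=11)
    a = generate_set(c)
    b = generate_set(c)
    assert a.sequences == b.sequences and a.seed == b.seed == 11
    c2 = generate_set(c, seed=12)
    assert c2.seed == 12


def test_max_sequences_short_circuits():
    c = global_constraints(10, 4, max_sequences=5)
    r = generate_set(c, seed=0)
    assert len(r) == 5 and not r.complete


def test_capacity_bound_holds_under_global_rules():
    for ls, lc in [(10, 4), (12, 4), (10, 5), (8, 3)]:
        r = generate_set(global_constraints(ls, lc), seed=1)
        assert r.complete
        assert len(r) <= max_set_size(ls, lc).n_s


def _all_sequences(ls):
    from itertools import product

    return ("".join(p) for p in product("ACGT", repeat=ls))


def _is_valid_addition(seq, constraints, members):
    """Full validity of one more sequence: every design rule, plus the
    criton-rule ban on self-complementary words (a palindromic window is its
    own anti-criton and can never be used)."""
    if any(is_palindrome(w) for w in windows(seq, constraints.criton_length)):
        return False
    return bool(check_sequence(seq, constraints, context=list(members)))


@pytest.mark.parametrize("ls,lc", [(4, 2), (6, 3)])
def test_complete_sets_are_maximal_by_exhaustive_oracle(ls, lc):
    c = global_constraints(ls, lc)
    r = generate_set(c, seed=5)
    assert r.complete and len(r) >= 1
    extra = [s for s in _all_sequences(ls) if _is_valid_addition(s, c, r.sequences)]
    assert extra == []


def test_members_mutually_valid():
    c = global_constraints(10, 4)
    r = generate_set(c, seed=9)
    for i, s in enumerate(r.sequences):
        others = r.sequences[:i] + r.sequences[i + 1 :]
        assert check_sequence(s, c, context=list(others)).ok


def test_stepwise_generation_with_included_sequences():
    # first step: strict stem limit; second step: relax the stem limit,
    # forbid guanine, include the first set — further sequences arise
    c1 = DesignConstraints(seq_length=15, criton_length=5, lhp=2, lsc=6, lsl=5,
                           gc_ends=True, max_sequences=14)
    first = generate_set(c1, seed=2)
    assert len(first) >= 10
    c2 = DesignConstraints(
        seq_length=15, criton_length=5, lhp=3, lsc=6, lsl=5, gc_ends=True,
        forbidden_motifs=("G",), included_sequences=first.sequences,
    )
    second = generate_set(c2, seed=3)
    assert len(second) >= 1
    assert all("G" not in s for s in second.sequences)
    for s in second.sequences:
        assert check_sequence(
            s, c2, context=list(first.sequences) + [t for t in second.sequences if t != s]
        ).ok


def test_generate_paired_tags_respects_neighbors():
    rng = np.random.default_rng(0)
    neighbors = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
    base = DesignConstraints(seq_length=12, criton_length=6, lhp=2, lsc=4, lsl=6,
                             lni=4)
    tags = generate_paired_tags(base, neighbors, seed=1)
    assert len(tags) == 3
    for tag, nb in zip(tags.sequences, neighbors):
        assert max_cross_hybridization(tag, nb) < 4  # own-neighbor foldback rule
    for tag in tags.sequences:
        for nb in neighbors:  # criton rule vs every neighbor
            assert max_cross_hybridization(tag, nb) < 6
    # and mutually
    assert max_cross_hybridization(tags.sequences[0], tags.sequences[1]) < 6
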