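# oligoset

Exhaustive design of maximum-size sets of mutually non-cross-hybridizing
DNA sequences, with independent control of intrastrand structure.

Applications that route molecules by hybridization — DNA microarray
TAG/anti-TAG systems, multiplexed single-base-extension genotyping, DNA
computing, sticky ends and capture probes on DNA origami — need many short
sequences that bind *only* their own complement. `oligoset` generates such
sets and audits existing ones.

## The model

Interstrand uniqueness follows the *criton* concept: every overlapping
word of length `L_c` (the criton length) may occur only once across the
whole set, and its reverse complement (anti-criton) may not occur at all.
No two strands can then form a duplex of `L_c` or more consecutive base
pairs. Since each sequence of length `L_s` contains `L_s − L_c + 1`
windows, and self-complementary words (which exist only for even `L_c`)
can never be used, the set size is bounded by

    N_s = ⌊ (4^L_c − P) / (2 (L_s − L_c + 1)) ⌋,   P = 4^(L_c/2) (even L_c), else 0.

Independently of `L_c`, the generator limits intrastrand structure:
palindromic (self-complementary) subsequences of length ≥ `lsc`, hairpin
stems of length ≥ `lhp` (two reverse-complementary non-overlapping arms),
and repeated subsequences of length ≥ `lsl` ("sliding") are forbidden, as
are arbitrary motifs (e.g. `{GGG, CCC}`), non-G/C terminal bases, and
words complementary to a paired neighboring sequence (`lni`, foldback
control for TAG–primer pairs).

Generation is an exhaustive randomized backtracking search: allowed basic
sequences (criton-length words) are filtered, strands are assembled
block-wise in random order with every rule re-checked on the growing
string, dead-end block prefixes are learned as nogoods and never
re-entered, and accepted strands surrender their words. A failed search is
therefore a proof that the set is **complete** — no further valid sequence
exists. A nearest-neighbor module predicts duplex formation free energies
(ΔG°37) with published parameter sets.

## Worked example

```python
from oligoset import audit_set, generate_set, global_constraints, max_set_size

constraints = global_constraints(10, 4)     # 10-mers, criton length 4
result = generate_set(constraints, seed=1)  # complete, reproducible
print(len(result), max_set_size(10, 4).n_s, result.complete)
print(audit_set(result.sequences, constraints).clean)
```

prints

```
14 17 True
True
```

Fourteen 10-mers were generated against a theoretical maximum of 17 (82%
yield); the search proved no fifteenth sequence exists under these
constraints, and the independent auditor confirms that no 4-base word
occurs twice (in either orientation) across the set and that every
intrastrand limit holds. The same run from the shell:

```sh
oligoset generate --length 10 --criton 4 --global-rules --seed 1 --out run
oligoset capacity --length 10 --criton 4     # -> 17
oligoset audit run.fasta --criton 4 --lhp 4 --lsl 4 --lsc 5
oligoset dg ACGTACGT                         # -> -8.28 kcal/mol
oligoset experiment size-distribution -L 20 -c 6 -n 10 --seed 0
```

The `examples/` directory holds one short narrative script per
capability: capacity grids, basic set design, the set-size cost of
tightening hairpin/repeat limits, TAG design against neighboring
sequences, duplex energies, and auditing published sequence sets (several
of which ship with the package, see
`oligoset.load_published_sets()`).

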