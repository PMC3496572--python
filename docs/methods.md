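# Methods

## Sequence model and conventions

Sequences are uppercase strings over {A, C, G, T}, written 5'→3'.
"Complement" always means the *reverse* complement: hybridization is
antiparallel, so a subsequence of one strand pairs with a subsequence of
another iff one equals the reverse complement of the other. Lowercase
input is normalized; any other character (including IUPAC codes such as N)
is rejected — the search is defined only over the four unambiguous bases.
Coordinates are 0-based half-open internally and 1-based inclusive in all
user-facing reports.

A *palindromic* (self-complementary) sequence equals its own reverse
complement and necessarily has even length: in an odd-length sequence the
central base would have to pair with itself. We treat self-complementarity
as the loop-size-zero special case of a hairpin, so forbidding stems of
length ≥ `lhp` (with the default minimum loop of 0) also forbids
palindromes of length ≥ `2·lhp`. `max_hairpin_stem` accepts a `min_loop`
argument for users who want a physically foldable loop (≥ 3), but the
design rules use loop ≥ 0 so that the stem rule dominates the palindrome
rule exactly.

## Design rules

One sequence is valid in the context of a set when all of the following
hold (`0` disables a limit):

* exact length `L_s`; GC count within `[⌊gc_min·L_s⌋, ⌈gc_max·L_s⌉]`
  (the floor/ceil convention defines "exact content" on lengths where the
  fraction is not an integer count); G/C terminal bases if `gc_ends`;
* no forbidden motif occurs (literal matching; complements are *not*
  auto-added — list both `GGG` and `CCC` if both are unwanted);
* no repeated subsequence of length ≥ `lsl` (same strand, same
  orientation, overlapping occurrences count);
* no palindromic subsequence of length ≥ `lsc`;
* no hairpin stem of length ≥ `lhp` (non-overlapping arms, loop ≥ 0);
* no criton (length-`L_c` window) of the sequence, nor its reverse
  complement, occurs among the criton windows of any other set member,
  included sequence or neighbor sequence. Within one strand, repetition of
  a word is governed solely by `lsl`/`lhp`, not by the criton rule —
  this is what makes `lsl > L_c` profitable (see below);
* no word of length ≥ `lni` whose reverse complement occurs in the paired
  neighbor sequence (foldback control). Words spanning the junction of a
  direct TAG–neighbor concatenation are not considered: the model assumes
  a molecular spacer between the two.

Self-complementary critons are unusable in principle (each is its own
anti-criton), so the generator never places one, in any window of any
strand. This is a property of the criton rules, not of `lsc`; it is also
what the capacity formula's palindromic-word subtraction assumes. The
standalone `check_sequence` used for auditing implements the listed rules
only, so third-party sets are not penalized for palindromic words their
design rules permitted.

Capacity: `N_s = ⌊(4^L_c − P) / (2(L_s − L_c + 1))⌋` with
`P = 4^(L_c/2)` for even `L_c`, else 0. The quotient is floored. Under
*global criton rules* (`lsl = lhp = L_c`; `lsc = L_c` for odd, `L_c + 1`
for even `L_c` — the regime of older design tools) this is an attainable
upper bound on the set size; with `lsl > L_c` single strands may reuse
words and sets can exceed it.

## The search

1. **Filter.** All `4^L_c` words are screened against the locally
   checkable rules (motifs, `lsc`, `lhp`, `lsl`, criton windows of
   included/neighbor sequences). If `L_s mod L_c = r > 0`, a remainder
   pool of r-mers is filtered the same way; remainder words are not
   critons and are constrained only through whole-string checks, matching
   the capacity formula, which counts `L_c`-words only.
2. **Assembly.** A strand grows left to right from randomly ordered basic
   sequences, the remainder block strictly last. After each appended block
   the whole string is re-validated incrementally: every rule is monotone
   under extension, so only the windows the new characters create need
   checking, and junction-spanning windows are screened like any others.
   A prefix is also abandoned early when its GC count can no longer reach
   the allowed band (pure pruning; cannot change the reachable set).
3. **Nogood learning.** When a block prefix admits no suffix block, it is
   recorded and never re-entered for the rest of this set's generation.
   This is sound because the constraints only tighten as sequences are
   accepted: a dead prefix under a shrinking pool stays dead. The store is
   cleared between independent sets.
4. **Acceptance.** A full-length valid strand is accepted; all its criton
   windows and their reverse complements are physically removed from the
   pool and banned from later strings (duplicates once).
5. **Completeness.** The assembly search is a systematic depth-first
   enumeration whose randomness only permutes exploration order, so a
   failed assembly *proves* that no further valid sequence exists; the set
   is then flagged complete. `max_sequences` short-circuits the loop
   early (and leaves the flag false). Because every failed search is
   already a proof, requesting completeness costs nothing beyond running
   to exhaustion.

**Randomization discipline.** The pool order is shuffled once per
assembly (one permutation per "trail"), and the depth-first search then
walks that order at every level. This choice is load-bearing for the
statistics: because deeper levels scan from the same permutation's head,
successive blocks within one strand are correlated, and when the
intrastrand repeat limit allows it (`lsl > L_c`) the search readily builds
strands that reuse a block — which is precisely the regime where larger
sets come from strands "spending" fewer words. Per-node independent
choices were evaluated and reproduce most distributions but not this one;
a single per-set order over-commits in the opposite direction. One
seedable NumPy generator drives all choices; a run is a pure function of
(constraints, seed), and the seed is recorded in the output metadata.

**Performance.** Candidate blocks at each node are prefiltered with a
vectorized necessary-condition mask over the encoded pool (availability of
every junction-spanning criton window, GC feasibility, terminal-base
demands, and — when `lsl ≤ L_c` — words already used in the growing
strand). The mask never rejects a block the exact incremental checker
would accept; survivors (a fraction of a percent near exhaustion) go
through the exact check. The lookup tables take `4^L_c` bytes and are used
for `L_c ≤ 12`; beyond that the search falls back to exact checks only.
Complete sets at `L_s = 20, L_c = 6` take ~0.5 s each on one CPU; the
search is practical up to `L_c ≈ 7` for complete sets, consistent with
the exponential growth of the word supply.

## Auditing

`audit_set` re-measures every property with standalone scans that share no
code with the generator: GC, terminal bases, motif hits, longest
palindrome, longest stem (first-occurrence map with the non-overlap
condition), longest repeat and, pairwise, the longest interstrand word in
both orientations (binary search over shared k-mer sets; both the
reverse-complement match and the same-orientation shared word violate
criton uniqueness). Violations are reported as (sequence id, rule,
measured, threshold); an empty list is equivalent to all maxima lying
strictly below their thresholds. Six published reference sets (and nine
comparison sets from other design tools) ship with the package and anchor
the auditor's expected outputs; mixed-length sets are audited with
per-sequence GC bounds.

## Thermodynamics

`duplex_dg37` evaluates the nearest-neighbor model for a strand paired
with its perfect reverse complement at 37 °C, 1 M Na+: initiation + sum of
dinucleotide stacks + terminal corrections + a symmetry correction for
self-complementary strands. The default parameter set is SantaLucia,
Allawi & Seneviratne (Biochemistry 35:3555, 1996): initiation
+1.82 kcal/mol, symmetry +0.4, and +0.4 per strand with a 5'-terminal
thymine — the "fraying" penalty that motivates the GC-ends design option.
The unified oligonucleotide set (SantaLucia, PNAS 95:1460, 1998) is also
shipped (`UNIFIED_1998`: per-end initiation 0.98/1.03, symmetry +0.43) and
is cross-checked in the test suite against Biopython's ΔH/ΔS tables.
Hairpin folding energies, mismatches, dangling ends, salt and temperature
corrections are out of scope; the auditor reports structural stem and
palindrome lengths instead of hairpin energies.

## Study conditions, problem sizes and what the tests show

The repeated-generation experiments regenerate the package's reference
statistics at reduced run counts chosen to keep the default test suite in
the minutes range: 200 complete sets for the (L_s=20, L_c=6) size
distribution (originally 10,000), 10 runs per point for the `lsl`/`lhp`
sweeps (as originally), 10,000 fast runs at (10, 4) in the acceptance
script, and a fixed 12-cell subgrid (L_c ∈ {4,5,6} × L_s ∈ {10,15,20,30})
for the average-yield check, selected a priori as a representative spread
of the full 124-cell grid (the subgrid's published average yield is 86.5%
vs 87.0% overall). `table1_grid` accepts the full ranges for users who
want the complete grid. Stochastic comparisons use bands of two published
standard deviations plus a two-standard-error allowance for the reduced
run counts; run counts are printed in every report.

All experiment inputs are generated in-package (constraints + seeds); no
external data is required. What passing tests show is therefore
*self-consistency and agreement with published statistics of the design
process*, not wet-lab behaviour of the oligos: the thermodynamic model
covers only perfect duplexes, and structural limits (stem/repeat lengths)
are proxies for, not measurements of, folding and cross-talk at assay
conditions.

## Degenerate inputs and tie-breaks

* `L_c = L_s`: single-block assembly; GC-ends and exact-GC checks apply to
  the lone block.
* Over-constrained designs where no basic sequence exists raise an
  over-constrained error before generation; running out of words during
  generation is not an error but normal completion.
* `max_internal_repeat`/`max_hairpin_stem` report 0 below length-2
  features; palindrome lengths are even by construction.
* Failure reporting in `check_sequence` runs cheapest-first (length, ends,
  GC, motifs, repeats, palindromes, stems, critons, neighbor) and reports
  the first failing rule.
* The experiment mode statistic breaks ties toward the smaller set size
  and always reports the full histogram; means use the sample (n−1)
  standard deviation, with sd reported as 0 (and flagged undefined) for a
  single run.

## Known limitations

Single-threaded; complete sets at `L_c ≥ 8` become expensive (word supply
grows as `4^L_c`). The nogood store is exact block prefixes, not
generalized subsets. Neighbor pairing assumes a spacer (no junction
words). RNA alphabets, IUPAC degenerate codes, melting temperatures and
two-state hairpin energetics are out of scope.
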