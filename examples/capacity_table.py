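"""Theoretical maximum set sizes for a grid of sequence/criton lengths.

Each sequence of length L_s consumes its L_s - L_c + 1 criton windows plus
their reverse complements from the 4**L_c word supply (minus the unusable
self-complementary words when L_c is even), which bounds the set size.
"""

from oligoset import max_set_size

print("L_s \\ L_c |" + "".join(f"{lc:>8}" for lc in (4, 5, 6, 7)))
print("-" * 42)
for ls in (10, 15, 20, 25, 30, 40):
    row = [max_set_size(ls, lc).n_s for lc in (4, 5, 6, 7)]
    print(f"{ls:9d} |" + "".join(f"{n:>8}" for n in row))
# Longer sequences consume more words each (fewer sequences fit); longer
# critons grow the word supply exponentially (many more sequences fit).
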