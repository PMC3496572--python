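"""Design address TAGs paired 1:1 with neighboring sequences.

Models the single-base-extension genotyping workflow: each TAG is tethered
next to a primer/flanking sequence, so words complementary to the *own*
neighbor are forbidden (foldback risk, lni), and no TAG may share a criton
with *any* neighbor or earlier TAG.
"""

import numpy as np

from oligoset import DesignConstraints, generate_paired_tags, max_cross_hybridization

rng = np.random.default_rng(7)
neighbors = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)]

base = DesignConstraints(
    seq_length=16, criton_length=6, lhp=2, lsc=4, lsl=6, lni=4,
    gc_ends=True, forbidden_motifs=("GGG", "CCC"),
)
tags = generate_paired_tags(base, neighbors, seed=1)

for i, (tag, nb) in enumerate(zip(tags.sequences, neighbors), 1):
    k = max_cross_hybridization(tag, nb)
    print(f"TAG {i}: {tag}   longest complementary run with its neighbor: {k} < 4")
# No TAG can fold back onto its neighbor with 4+ consecutive base pairs,
# and every 6-base word is unique across all TAGs and neighbors.
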