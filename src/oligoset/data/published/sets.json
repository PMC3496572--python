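{
 "arita_15_20nt": {
  "description": "comparison set by Arita et al. (nine 15-nt + three 20-nt)",
  "file": "arita_15_20nt.fasta",
  "lengths": [
   15,
   20
  ],
  "n_sequences": 12,
  "origin": "comparison",
  "params": {
   "criton_length": 10,
   "gc_ends": false,
   "lhp": 5,
   "lsc": 6,
   "lsl": 8
  }
 },
 "faulhammer_15nt": {
  "description": "15-nt comparison set by Faulhammer et al.",
  "file": "faulhammer_15nt.fasta",
  "lengths": [
   15
  ],
  "n_sequences": 20,
  "origin": "comparison",
  "params": {
   "criton_length": 8,
   "gc_ends": false,
   "lhp": 5,
   "lsc": 8,
   "lsl": 5
  }
 },
 "feldkamp_15_20nt": {
  "description": "comparison set by Feldkamp et al. (nine 15-nt + three 20-nt)",
  "file": "feldkamp_15_20nt.fasta",
  "lengths": [
   15,
   20
  ],
  "n_sequences": 12,
  "origin": "comparison",
  "params": {
   "criton_length": 5,
   "gc_ends": false,
   "lhp": 5,
   "lsc": 6,
   "lsl": 4
  }
 },
 "feldkamp_15nt": {
  "description": "15-nt comparison set by Feldkamp et al.",
  "file": "feldkamp_15nt.fasta",
  "lengths": [
   15
  ],
  "n_sequences": 20,
  "origin": "comparison",
  "params": {
   "criton_length": 5,
   "gc_ends": false,
   "lhp": 5,
   "lsc": 6,
   "lsl": 5
  }
 },
 "feldkamp_20nt": {
  "description": "20-nt comparison set by Feldkamp et al.",
  "file": "feldkamp_20nt.fasta",
  "lengths": [
   20
  ],
  "n_sequences": 14,
  "origin": "comparison",
  "params": {
   "criton_length": 5,
   "gc_ends": false,
   "lhp": 5,
   "lsc": 6,
   "lsl": 5
  }
 },
 "feldkamp_20nt_b": {
  "description": "20-nt comparison set by Feldkamp et al. (second comparison)",
  "file": "feldkamp_20nt_b.fasta",
  "lengths": [
   20
  ],
  "n_sequences": 7,
  "origin": "comparison",
  "params": {
   "criton_length": 5,
   "gc_ends": false,
   "lhp": 4,
   "lsc": 6,
   "lsl": 4
  }
 },
 "feldkamp_22nt": {
  "description": "22-nt comparison set by Feldkamp et al. (DNASequenceGenerator)",
  "file": "feldkamp_22nt.fasta",
  "lengths": [
   22
  ],
  "n_sequences": 14,
  "origin": "comparison",
  "params": {
   "criton_length": 5,
   "gc_ends": false,
   "lhp": 5,
   "lsc": 6,
   "lsl": 5
  }
 },
 "ref15_20_included": {
  "description": "nine 15-nt sequences designed first, then four 20-nt sequences designed with the 15-nt set included; GC ends, lhp=2",
  "file": "ref15_20_included.fasta",
  "lengths": [
   15,
   20
  ],
  "n_sequences": 13,
  "origin": "reference",
  "params": {
   "criton_length": 5,
   "gc_ends": true,
   "lhp": 2,
   "lsc": 4,
   "lsl": 5
  }
 },
 "ref15_stepwise": {
  "description": "20 15-nt sequences designed stepwise: 14 at lhp=2, then 6 more at lhp=3 with guanine forbidden and the first 14 included; GC ends",
  "file": "ref15_stepwise.fasta",
  "lengths": [
   15
  ],
  "n_sequences": 20,
  "origin": "reference",
  "params": {
   "criton_length": 5,
   "gc_ends": true,
   "lhp": 3,
   "lsc": 6,
   "lsl": 5
  }
 },
 "ref20_gc_ends": {
  "description": "20-nt reference set with GC ends and hairpin stems limited to 1 bp",
  "file": "ref20_gc_ends.fasta",
  "lengths": [
   20
  ],
  "n_sequences": 16,
  "origin": "reference",
  "params": {
   "criton_length": 5,
   "gc_ends": true,
   "lhp": 2,
   "lsc": 4,
   "lsl": 5
  }
 },
 "ref20_low_sliding": {
  "description": "seven 20-nt sequences with sliding limited to 2 bases (lsl=3), hairpin stems to 1 bp, GC ends",
  "file": "ref20_low_sliding.fasta",
  "lengths": [
   20
  ],
  "n_sequences": 7,
  "origin": "reference",
  "params": {
   "criton_length": 5,
   "gc_ends": true,
   "lhp": 2,
   "lsc": 4,
   "lsl": 3
  }
 },
 "ref20_short_criton": {
  "description": "seven 20-nt sequences at criton length 4 (no 4-base cross-hybridizations), lhp=3, lsl=6",
  "file": "ref20_short_criton.fasta",
  "lengths": [
   20
  ],
  "n_sequences": 7,
  "origin": "reference",
  "params": {
   "criton_length": 4,
   "gc_ends": false,
   "lhp": 3,
   "lsc": 4,
   "lsl": 6
  }
 },
 "ref22_hairpin_free": {
  "description": "22-nt reference set designed with the original implementation of this algorithm: hairpin stems limited to 1 bp (lhp=2) at criton length 5",
  "file": "ref22_hairpin_free.fasta",
  "lengths": [
   22
  ],
  "n_sequences": 14,
  "origin": "reference",
  "params": {
   "criton_length": 5,
   "gc_ends": false,
   "lhp": 2,
   "lsc": 4,
   "lsl": 5
  }
 },
 "shin_20nt": {
  "description": "20-nt comparison set by Shin et al.",
  "file": "shin_20nt.fasta",
  "lengths": [
   20
  ],
  "n_sequences": 7,
  "origin": "comparison",
  "params": {
   "criton_length": 6,
   "gc_ends": false,
   "lhp": 6,
   "lsc": 6,
   "lsl": 7
  }
 },
 "tanaka_20nt": {
  "description": "20-nt comparison set by Tanaka et al.",
  "file": "tanaka_20nt.fasta",
  "lengths": [
   20
  ],
  "n_sequences": 14,
  "origin": "comparison",
  "params": {
   "criton_length": 9,
   "gc_ends": false,
   "lhp": 5,
   "lsc": 10,
   "lsl": 7
  }
 }
}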