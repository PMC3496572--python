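>arita_15_20nt|1
CCGTCTTCTTCTGCT
>arita_15_20nt|2
TTCCCTCCCTCTCTT
>arita_15_20nt|3
CGTCCTCCTCTTGTT
>arita_15_20nt|4
CCCCTTCTTGTCCTT
>arita_15_20nt|5
TGCCCCTCTTGTTCT
>arita_15_20nt|6
CTCCTCTTCCTTGCT
>arita_15_20nt|7
CTTCTCCCTTCCTCT
>arita_15_20nt|8
CCTTCCTTCCCTCTT
>arita_15_20nt|9
TCCCCTTGTGTGTGT
>arita_15_20nt|10
GAGAGAGAGGCCCCCTATCC
>arita_15_20nt|11
GAAGAGAAGGGCACCCCTCC
>arita_15_20nt|12
GTGGTGTTGCGTCCCTTCCC
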