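>feldkamp_20nt|1
TAGTCGCGTGATTTGGAAGG
>feldkamp_20nt|2
GCTGTCTTTCGTCAATACCG
>feldkamp_20nt|3
CTGAACGGAATCTAGTAGCG
>feldkamp_20nt|4
GTCTACGGTTCTCTTACGCT
>feldkamp_20nt|5
AAAGCCGTCGTTTAAGGAGC
>feldkamp_20nt|6
AATCGCAGTACAGATGGTGG
>feldkamp_20nt|7
GGATGACCAGAGCACTTCAA
>feldkamp_20nt|8
TACGTCTCGAACTGATAGCC
>feldkamp_20nt|9
TGATCTTGTAAAGGCCAGGC
>feldkamp_20nt|10
TACGATACTTGGCGAGCCAT
>feldkamp_20nt|11
TGCAGAAAAACTATGCCGCC
>feldkamp_20nt|12
GCGCGGACAATTCATTGGTT
>feldkamp_20nt|13
CCGCAATCCGGTGAAATTAG
>feldkamp_20nt|14
CTTAGGCAGGTGCCACATAT
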