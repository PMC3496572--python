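>tanaka_20nt|1
ATGTACGTGAGATGCAGCAG
>tanaka_20nt|2
ATCACTACTCGCTCGTCACT
>tanaka_20nt|3
AGATGATCAGCAGCGACACT
>tanaka_20nt|4
TCTGTACTGCTGACTCGAGT
>tanaka_20nt|5
ACATCGACACTACTACGCAC
>tanaka_20nt|6
GCTGACATAGAGTGCGATAC
>tanaka_20nt|7
TGTGCTCGTCTCTGCATACT
>tanaka_20nt|8
TCAGAGATACTCACGTCACG
>tanaka_20nt|9
CGAGTAGTCACACGATGAGA
>tanaka_20nt|10
CGAGACATCGTGCATATCGT
>tanaka_20nt|11
AGACGAGTCGTACAGTACAG
>tanaka_20nt|12
TATAGCACGAGTGCGCGTAT
>tanaka_20nt|13
GATCTACGATCATGAGAGCG
>tanaka_20nt|14
GACAGAGCTATCAGCTACTG
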