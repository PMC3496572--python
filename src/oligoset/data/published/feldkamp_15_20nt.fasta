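>feldkamp_15_20nt|1
AAAGCCGTCGTTTCC
>feldkamp_15_20nt|2
TTGTGGTACTCTGCG
>feldkamp_15_20nt|3
TATTAGATGGCCGCC
>feldkamp_15_20nt|4
CTAGCTCCTTTGTCG
>feldkamp_15_20nt|5
GCATTGTAGTGGCTG
>feldkamp_15_20nt|6
GGCATATAGCGTGAC
>feldkamp_15_20nt|7
GTTATTGCGACCTCG
>feldkamp_15_20nt|8
AGTCATGGACCAACG
>feldkamp_15_20nt|9
GAACGGTTACCGATC
>feldkamp_15_20nt|10
AAAGACGTGTGAAGTGCGCT
>feldkamp_15_20nt|11
GACGAAAGTTCAGCAGCGAA
>feldkamp_15_20nt|12
TGTTAAAATCAGGCTCGCGC
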