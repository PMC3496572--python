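>feldkamp_22nt|1
CCTGCGTCGTTTAAGGAAGTAC
>feldkamp_22nt|2
CAGCCAAGATTCTTTTACCGCC
>feldkamp_22nt|3
CCATCATGTGTGCCGAGATATG
>feldkamp_22nt|4
CTTCTCCTAACTGCACGGAATG
>feldkamp_22nt|5
GGTCCGGTCATAAAGCGATAAG
>feldkamp_22nt|6
GTCCTCGCCTAGTGTTTCATTG
>feldkamp_22nt|7
GGATCTGGCGCATAGACAATTC
>feldkamp_22nt|8
CACGTCACTGTTAATCCGAAGC
>feldkamp_22nt|9
GTGGAAAGTGGCAATCGTGAAG
>feldkamp_22nt|10
GGACGAATACAAAGGCTACACG
>feldkamp_22nt|11
CAAGGTCTGCTTGATTTGGAGG
>feldkamp_22nt|12
GTTTTGAACGTAGTAGAGCCGG
>feldkamp_22nt|13
GTAGGTGTCGGTGCGAAATTAG
>feldkamp_22nt|14
CTAGAACCGTTACGAGTTTGCG
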