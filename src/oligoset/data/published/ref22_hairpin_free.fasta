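>ref22_hairpin_free|1
GCTCATTTTACACTCTCCACCG
>ref22_hairpin_free|2
CACACGGAGGCACAGAATAAAC
>ref22_hairpin_free|3
GAACAGCGAAGAGATAGGAAGG
>ref22_hairpin_free|4
CCTTACTCGCCTTTCACATTCC
>ref22_hairpin_free|5
CAACTCACGCCACTACATCAAC
>ref22_hairpin_free|6
CAAGCCGTCAATAGTCCAAGTC
>ref22_hairpin_free|7
CTGCTGAACCTGATACCGAAAC
>ref22_hairpin_free|8
CAGTATTTCCAGTCAGTTCCGC
>ref22_hairpin_free|9
CCTGTCGTTTTCTATGCTCCTG
>ref22_hairpin_free|10
CCTGCCGATGACCTACTTTTTG
>ref22_hairpin_free|11
CCGTTCTTTGTCCTTGCTTCTC
>ref22_hairpin_free|12
GTGATTGGCTGGTGTTGGTTTG
>ref22_hairpin_free|13
GCTCGTGGTCTTGTTATGTCTG
>ref22_hairpin_free|14
GTAGATTTGAGGTGCGTTGTGG
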