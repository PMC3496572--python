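>ref20_gc_ends|1
GAGAAGGAACACGATACAGC
>ref20_gc_ends|2
CCTTACACATTTCTTCCGCC
>ref20_gc_ends|3
CACAATCAACTCTACCGCTC
>ref20_gc_ends|4
CCTGTCCTATCTTTCGCTTC
>ref20_gc_ends|5
CTGGCTATGGAAACTGAACG
>ref20_gc_ends|6
CTCGGTCTAAATCTGCTCTC
>ref20_gc_ends|7
GCCGTTATCCTCTGTTTGTC
>ref20_gc_ends|8
GGTTTATTGAGGTTGCGAGG
>ref20_gc_ends|9
CCTCCGTATTTGCCTTGTTG
>ref20_gc_ends|10
GTTGTAGTTCGTTGGTGGTC
>ref20_gc_ends|11
CTTCGGCTGGTTCTATTCTG
>ref20_gc_ends|12
GGCTCACTCATCACACTAAC
>ref20_gc_ends|13
CCTTTACGCCTGACTTTGAC
>ref20_gc_ends|14
CCTGCGTCTTATGTCTCTTG
>ref20_gc_ends|15
GCGTGAATGAAGTGGAGTAG
>ref20_gc_ends|16
GGATTACTTGCTTGGACTGG
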