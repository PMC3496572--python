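>faulhammer_15nt|1
ATCCTCCACTTCACA
>faulhammer_15nt|2
CTATTTCTCCACACC
>faulhammer_15nt|3
CACCCTTTCTCCTCT
>faulhammer_15nt|4
TCCTCACATTACTTA
>faulhammer_15nt|5
ACTTCCTTTATATCC
>faulhammer_15nt|6
TCCACCAACTACCTA
>faulhammer_15nt|7
AACTCTCAAATTCAA
>faulhammer_15nt|8
ACCTTACTTTCCATA
>faulhammer_15nt|9
CTCTTACTCAATTCT
>faulhammer_15nt|10
GTACATTCTCCCTAC
>faulhammer_15nt|11
TTATAACAAACATCC
>faulhammer_15nt|12
TTTTAAATTTCACAA
>faulhammer_15nt|13
ATAATCACATACTTC
>faulhammer_15nt|14
CATTCCTTATCCCAC
>faulhammer_15nt|15
CATATCAACATCTTA
>faulhammer_15nt|16
TTAAAATCTTCCCTC
>faulhammer_15nt|17
CTAACCTTTACTTCA
>faulhammer_15nt|18
GCTTCAAACAATTCC
>faulhammer_15nt|19
ACATAACCCTCTTCA
>faulhammer_15nt|20
CATAATCTTATATTC
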