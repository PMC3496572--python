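>ref20_low_sliding|1
CAAAGAACCGACATAGCCAC
>ref20_low_sliding|2
GAACGGCAGGAGACAAATAC
>ref20_low_sliding|3
CATAAGAGGAAACAGCACGG
>ref20_low_sliding|4
GTTCGTCCTATTGCTCTGTG
>ref20_low_sliding|5
GTCGTGTTGCCTTTCTATCC
>ref20_low_sliding|6
GGTTTATTCTCGGCTTGTGG
>ref20_low_sliding|7
GGCTCGTTTGGTGTATCTTC
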