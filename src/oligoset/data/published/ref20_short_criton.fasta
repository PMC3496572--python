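>ref20_short_criton|1
CCAACCAAACCACCAATCTC
>ref20_short_criton|2
CTGTCGTCGTGTCTTCTTCA
>ref20_short_criton|3
GCAGGCAGGTCAAGGTAAAT
>ref20_short_criton|4
ATCCGCCATAATAAGTCCGC
>ref20_short_criton|5
CTTTCGGCTCCTAACATTCG
>ref20_short_criton|6
GAGTGAGTTCCAGAGTATCG
>ref20_short_criton|7
TTGTAGCATCATCAGCGAGG
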