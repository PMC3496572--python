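>shin_20nt|1
AGGCGAGTATGGGGTATATC
>shin_20nt|2
TTATGATTCCACTGGCGCTC
>shin_20nt|3
CTTCGCTGCTGATAACCTCA
>shin_20nt|4
CGCTCCATCCTTGATCGTTT
>shin_20nt|5
ATCGTACTCATGGTCCCTAC
>shin_20nt|6
GAGTTAGATGTCACGTCACG
>shin_20nt|7
CCTGTCAACATTGACGCTCA
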