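>feldkamp_20nt_b|1
TAGTCGCGTGATTTGGAAGG
>feldkamp_20nt_b|2
TTACACTTGAAGCTGGCTCG
>feldkamp_20nt_b|3
CTTCGTGTCGGCCATCATAT
>feldkamp_20nt_b|4
AAAGCCGTCGTTTAAGGAGC
>feldkamp_20nt_b|5
GGTTCTTACGCTCTACTGCA
>feldkamp_20nt_b|6
TACGTCTCGAACTGATAGCG
>feldkamp_20nt_b|7
TCATGTTGGCACCGTATGCA
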