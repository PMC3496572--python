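>feldkamp_15nt|1
CTTCTCTCACCTATA
>feldkamp_15nt|2
GGCAAGAGGAATAAT
>feldkamp_15nt|3
GCGAAAATTAACTCC
>feldkamp_15nt|4
GATCCGGTTACTAAA
>feldkamp_15nt|5
ACCTGACTCGTAATA
>feldkamp_15nt|6
TAAGTATATCGTGCC
>feldkamp_15nt|7
GTCTGAGCTGATAAA
>feldkamp_15nt|8
GTACCGTTGAATTGT
>feldkamp_15nt|9
TGCGACTATGTTATG
>feldkamp_15nt|10
TTACAGCGTTTTACC
>feldkamp_15nt|11
AAAGCCGTCAAATAC
>feldkamp_15nt|12
TACCTTTTTGTCTCG
>feldkamp_15nt|13
ACAGGCGTATCTAAT
>feldkamp_15nt|14
AGTGACACTAGCATT
>feldkamp_15nt|15
ATGAGGCAGTCTTTA
>feldkamp_15nt|16
AAGCTATTGATTGGC
>feldkamp_15nt|17
CACTTGAGTACAACA
>feldkamp_15nt|18
GGATGTCCTTGTTTA
>feldkamp_15nt|19
ACCAAACCATGATGA
>feldkamp_15nt|20
TGGTAGGCCATTTAA
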