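>ref15_stepwise|1
CCTACAAATCAACTC
>ref15_stepwise|2
CTAAACACATCCAAC
>ref15_stepwise|3
GCAGAACAAGATAAG
>ref15_stepwise|4
CCTTCACTTACATTC
>ref15_stepwise|5
CTCTCACAATCTAAC
>ref15_stepwise|6
CAATTTAACCTCCTC
>ref15_stepwise|7
CTTCCATATACACTC
>ref15_stepwise|8
CCACACCTTAATATC
>ref15_stepwise|9
CTATAATTCTCCACC
>ref15_stepwise|10
CGTTGTCTCTATTTC
>ref15_stepwise|11
GTTCAGTATTCGTTC
>ref15_stepwise|12
GTAGCGAAGAAAATG
>ref15_stepwise|13
GGTTGCGTTTTATTG
>ref15_stepwise|14
CATCGTCAAGTAAAG
>ref15_stepwise|15
CTTTGGTCTGTTATG
>ref15_stepwise|16
GTCTTTTTGCTTTCG
>ref15_stepwise|17
GCAGTTTCATAGTTC
>ref15_stepwise|18
CTTCTACTACCTATC
>ref15_stepwise|19
GATTAGTGGTTTGAG
>ref15_stepwise|20
CTCATCATTACCATC
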