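>ref15_20_included|1
GAGAGAAACGGCAAC
>ref15_20_included|2
CGCAAACTCACCTAC
>ref15_20_included|3
GCCTTTACATCTCCG
>ref15_20_included|4
CAGAACGACAAAGCC
>ref15_20_included|5
CATACGAAGCACACC
>ref15_20_included|6
CCAGCCGATAACAAC
>ref15_20_included|7
GACCAACAGCAAGAC
>ref15_20_included|8
CAAGCGTCATCCAAG
>ref15_20_included|9
CACGCCATAAACCAG
>ref15_20_included|10
CTACACTCTTCACTTCCACC
>ref15_20_included|11
GCCTCATTCTTACCTCCTTC
>ref15_20_included|12
GAGACCGAAAGATAGCAGAG
>ref15_20_included|13
CAACCGCTCAAATCTACTCC
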