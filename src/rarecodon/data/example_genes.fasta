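>synthetic_example_0000 synthetic stand-in example gene
TCCTCGAACACTGCGCAGTCTCGACTATTGTACTCTGGCAGGTCTTCCAATCCAACAATATTTGGGCTTT
CGCGTCAGATTACCAGATTACTGAGCCCTCTCACCGCAGCGATTATGGGGCAGTTGTTGTCAGTACAGCT
AACGCGCAGCCCTGCCATAGAATTTAAGACGCCCGGCGTACGAATCACGAGCGCCACTTCGAGGACTAGG
GAGTTTTTTTCACTAACGCCTTTTAATGCGATGACTTCTAGCGATATCATAGTAATTAATGCTTCAACTT
TGTACGGGTTTTGTTCGCGCAGGGGCCATTTCCGCGAGGACGACGGATACTGCAACCTCGGCGTTACCTA
CACTATAAAGGCTCGACTCTGGACCTTTGTGCGTGGTTCC
>synthetic_example_0001 synthetic stand-in example gene
TTTTCTGTTAATCAACGCGCACACTATTACATCACTGTGCCCCGACACAGTAAGTTGCATCCTCGATGCT
CTTCGACACCGAAGCAGGACAAGTGCTACAGCTTACACTCGTTTGTCTCTCGTCGTCTCATTCTGCACGA
CAGGACCCGTAGGAGATATCCGACGCTTCACACGGCCAATGCTGTCGTTCCCGAGAGATTCACAACAATC
CTTGACGAAGCAGCCTCGAAGGCTACTCTTATCCAGGTAGTCTGCTGTCAGTACGCTGTACACTTTCGGG
CGCAAGAGACCCCCAGCTTCAAGTCTGTATTCCACTTGAGGCGCACGCGCGAAGGACGCAGACCGGACTC
GTGGCCGTTCGAGCGCACTGGGATGGGAGTAATCCGCCTCGGGTACCAGGCAATTCCC
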