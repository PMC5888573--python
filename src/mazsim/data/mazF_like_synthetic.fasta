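>mazF_like_synthetic synthetic stand-in CDS carrying the 9 ACA sites of the toxin cistron (not the genomic sequence)
ATGTGGTGCTCGTGCACCTCGTTCATTAGGACGTCCTTCGCTGGCTCCAAGACATGTAGC
TTTTCTCCCCTTTCGTGGACGGGGCTCCGCTCGGTCCGTACAGATTCTACTTGTTCGGAT
GAGCCGATTCCCTATCGGTTTCGGACACGTGTTCGCTTTGGGACATTCGCTGTCTTGCCC
ACAGTCATGAAGGCCGCCGTGTGTACAATTGCCACCACCACTGTTTGGCCTACAACGAGC
TTGAGGGGTGGCCTGCTTGTTTCGCTTGGTAGCTTCGCTGTCGTTATTGTTTTGGCCCCG
TTCTATACAGTGTGCTATCGGTCCACATTCTAA
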