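>mazE_like_synthetic synthetic stand-in CDS carrying the 2 ACA sites of the antitoxin cistron (not the genomic sequence)
ATGAGCAGCACAGAGGCTGCTGTGAATCTTAGGCGTTTCGCCACCGCCAGCGTTTTCTTT
GGCTGCCGGAGCGAGCTGGGTTTTCCCTGCAGCCGCTCCATTGGTCTGGATTTCTCGTCT
GCCTTTTTTAGCATCCCGGCCTCGCTTACACGCTTCGCTGTGATGGCTTCCTGGTGCTTG
AGCTATCTTGTCCCCAAGACGTTGTGGCCGCTCATGAGGTGCGGTACGATCGCGTGGTTT
ATCTAA
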