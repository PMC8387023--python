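>pAWM36 CMG helicase assay template, ScaI-linearised
AGTACTCAACCAAGTCATTCTGAGAATAGTGTATGCGGCGACCGAGTTGCTCTTGCCCGGCGTCAATACG
GGATAATACCGCGCCACATAGCAGGACTTTAAAAGTGCTCATCATTGGAAAACGTTCTTCGGGGCGAAAA
CTCTCAAGGATCTTACCGCTGTTGAGATCCAGTTCGATGTAACCCACTCGTGCACCCAACTGATCTTCAG
CATCTTTTACTTTCACCAGCGTTTCTGGGTGAGCAAAAACAGGAAGGCAAAATGCCGCAAAAAAGGGAAT
AAGGGCGACACGGAAATGTTGAATACTCATACTCTTCCTTTTTCAATATTATTGAAGCATTTATCAGGGT
TATTGTCTCATGAGCGGATACATATTTGAATGTATTTAGGGGAATAAACAAATAGGGGTTCCGCGCACAT
TTCCCCGAAAAGTGCCACCTGACGTCTAAGAAACCATTATTATCATGACATTGGCCTATAAAAATAGGCG
TATCACGAGGCCCTTTCGTCTCGCGCGTTTCGGTGATGACGGTGAAAACCTCTGACACATGCAGCTCCCG
GAGACGGTCACAGCTTGTCTGTAAGCGGATGCCGGGAGCAGACAAGCCCGTCAGGGCGCGTCAGCGGGTG
TTGGCGGGTGTCGGGGCTGGCTTAACTATGCGGCATCAGAGCAGATTGTACTGAGAGTGCACCATATGCG
GTGTGAAATACCGCACAGATGCGTAAGGAGAAAATACCGCATCAGGCGCCATTCGCCATTCAGGCTGCGC
AACTGTTGGGAAGGGCGATCGGTGCGGGCCTCTTCGCTATTACGCCAGCTGGCGAAAGGGGGATGTGCTG
CAAGGCGATTAAGTTGGGTAACGCCAGGGTTTTCCCAGTCACGACGTTGTAAAACGACGGCCAGTGAATT
CCTCGATTTTTTTATGTTTAGTTTCGCGGACGACGGTTTCGAGGTGGCGGTCTGGACCACGCCGGAGAGC
GTCGAAGCGGAGGCGGTGTTCGCCGAGATCGGCTCGCGCAAAGCCGAGTTGAGCGAACTAAACATAAAAA
TACAGCATCAGATGGTAGGCCTCCTGGCGCCGCACCGGCCTCAGCATCCGGTACCTCAGCTGGCCACATC
ACTGTCTTTCTTATGACGGTACTACCGGTGTTCACTGCACCAAGGTAACACTCATTAAATTAAGGTTAAA
TTAATCTACACAATTCTCTTTTGCTATTGGTACCGGATTCTCCAGCTCTGACTTCAGCGTCTCTGAAGGA
ATCTTTGCAGGTGCTTACGCTTACTACCTAAACTACAATGGTGTTGTCGCTACTAGTGCCGCTTCTTCAA
CCACTGGATCTGGTCCTAGGGCTTCGGTCCGCCCCTACTTCAGCGCCATTCGCCATTCAGGCTGCGCAAC
TGTTGGGAAGGGCGATCGGTGCGGGCCTCTTCGCTATTACGCCAGCTGGCGAAAGGGGGATGTGCTGCAA
TTCGGTTAAGTTAAGTTAAGGTTAAAGAAGCTAACGCCAGGGTTTTCCCAGTCACGATTCGGTGCTTCCG
TTACCGGTTCAACTGCTTCCACTTCATGGGCTACTTTTTGGACCGGAACGGCTGGTACTATCGGCCTGGT
ATCATCCTTTACCGAAGCAACATCTGTTTACACTACAACACTAGACCAAGCACAGTCGTAGTTTCTTGTT
CAGAGATGACTCCAATGGTAACGTCTATACCATTACCACAATCATTAAGTTAAATTAAGTTAATCAAACC
GTTCCATGCTCATCCACTACCGCCACTATTACTTCTTGTGATGAAACTGGATGTCACGTTAGTACATCAA
CCGGTGCTGTTGTAACTGAAACCGTTTCTTCCAAGGCATACACAACTGCCAAAGTAACTCGTTGTGACGC
CAATCAGCTTGTCTGTAAGCGGATGCCGGGAGCAGACAAGCCCGTCAGGGCGCGTCAGCGGGTGTTGGCG
GGTGTCGGGGCATGGTTAAAGTTAACTTAAATTAAGGTACGCGGCATCAGAGCAGATTGTACTGAGAGTG
CACCATATGCGGTGTGAAATACCGCACAGATGCGTAGGCTCAATGTAACTTAGCCACTGTCAATTGGGAA
TGTTCCAGGGATTCATGGACAACAACTGCAACTGGAGTATCATACACCACTGTCACCGTAACCCACTGTG
ACGACAATGGCTGTAACACCAAGACTAAGCTCCTGAAGCTACCACCACAACTATCGCCCACCAGGACCAC
CGTCACCTTTAGTGATGACAATGAAGGTAAGACCTTGGGTGAGTCTGGTCCAGCGGAGGGCCACTACTGT
TTCTCCAAAGACATACACCACCGCTACTGTTACTCAGGGGGATAAAAATGCCTGCCTCACCAAGACTGTC
ACTTCTGAATGTCCTGAAGAAACTTCAGCAACTACTACTGTCACTTCTGAGGGTTCTAAAGCAACCTCAT
TGAGTCGACGCGGGGGCGACGATTAACCTTAACGTTAAGTTAAGCTAGCACGACTACGCATCCCTCTGAC
TACTTCTCGGGGTGGGACTATACTGGTACCGATACGGGCTGTGATGACAACGATGTGTAGAACTGGGACA
ATCAGATCTGAGGCCCCTGAAGCCACAACGGGTACTGTTTCTAACAACAGATACAACATGGAGGGCCAAC
ATTGTCACAATAGAAGCTCCGCCAGAAACAGTAGAAACTTCAGAAACCAGTGCTGCCCCTAAGGACATAC
ACTACTGCCACTGGTTACTCAATGGTTTAGAGGGTGGTTGCCACGTCAAGATAATCACCTCTAAAATACC
TGAAGCTACTTCAACCGTCACGGGTGCTTCTCCAAAACGGCCTTACATAGCCGGATACAGTGACTTTGAC
AGGTTTGCGGGGCACAGCAATGACTTGCATAGCTGCGTGCGGGGGAAGGAACTCTTGCGTCTCACTGCCC
GCTTTCCAGTCGGGAAACCTGTCGTGCCATTATGGTTAACTTAAGTTAATTTAAGCTATCGGCCAACGCG
CGGGGAGAGGCGGTTTGCGTATTGGGCGCTCTTCCGCTTCCTCGCTCAGTGAGTATCTCTGCTTGACGAC
CCCTTGGCGCAGAGGTGCTGGCCGCGTGCTAAGTTGAAGCGGCTGCACTGCTGCAAGGTCCGTCACGGAG
GCGTCGGACCGGCAGGAGCACTAGCCCATCGACCCGTACGGGAACACTCTATATCGCTCTCGGACGGACA
TTCTGGATCCTCTAGAGTCGACCTGCAGGCATGCAAGCTTGGCGTAATCATGGTCATAGCTGTTTCCTGT
GTGAAATTGTTATCCGCTCACAATTCCACACAACATACGAGCCGGAAGCATAAAGTGTAAAGCCTGGGGT
GCCTAATGAGTGAGCTAACTCACATTAATTGCGTTGCGCTCACTGCCCGCTTTCCAGTCGGGAAACCTGT
CGTGCCAGCTGCATTAATGAATCGGCCAACGCGCGGGGAGAGGCGGTTTGCGTATTGGGCGCTCTTCCGC
TTCCTCGCTCACTGACTCGCTGCGCTCGGTCGTTCGGCTGCGGCGAGCGGTATCAGCTCACTCAAAGGCG
GTAATACGGTTATCCACAGAATCAGGGGATAACGCAGGAAAGAACATGTGAGCAAAAGGCCAGCAAAAGG
CCAGGAACCGTAAAAAGGCCGCGTTGCTGGCGTTTTTCCATAGGCTCCGCCCCCCTGACGAGCATCACAA
AAATCGACGCTCAAGTCAGAGGTGGCGAAACCCGACAGGACTATAAAGATACCAGGCGTTTCCCCCTGGA
AGCTCCCTCGTGCGCTCTCCTGTTCCGACCCTGCCGCTTACCGGATACCTGTCCGCCTTTCTCCCTTCGG
GAAGCGTGGCGCTTTCTCATAGCTCACGCTGTAGGTATCTCAGTTCGGTGTAGGTCGTTCGCTCCAAGCT
GGGCTGTGTGCACGAACCCCCCGTTCAGCCCGACCGCTGCGCCTTATCCGGTAACTATCGTCTTGAGTCC
AACCCGGTAAGACACGACTTATCGCCACTGGCAGCAGCCACTGGTAACAGGATTAGCAGAGCGAGGTATG
TAGGCGGTGCTACAGAGTTCTTGAAGTGGTGGCCTAACTACGGCTACACTAGAAGAACAGTATTTGGTAT
CTGCGCTCTGCTGAAGCCAGTTACCTTCGGAAAAAGAGTTGGTAGCTCTTGATCCGGCAAACAAACCACC
GCTGGTAGCGGTGGTTTTTTTGTTTGCAAGCAGCAGATTACGCGCAGAAAAAAAGGATCTCAAGAAGATC
CTTTGATCTTTTCTACGGGGTCTGACGCTCAGTGGAACGAAAACTCACGTTAAGGGATTTTGGTCATGAG
ATTATCAAAAAGGATCTTCACCTAGATCCTTTTAAATTGGAAATGAAGTTTTAAATCAATCTAAAGTATA
TATGAGTAAACTTGGTCTGACAGTTACCAATGCTTAATCAGTGAGGCACCTATCTCAGCGATCTGTCTAT
TTCGTTCATCCATAGTTGCCTGACTCCCCGTCGTGTAGATAACTACGATACGGGAGGGCTTACCATCTGG
CCCCAGTGCTGCAATGATACCGCGAGACCCACGCTCACCGGCTCCAGATTTATCAGCAATAAACCAGCCA
GCCGGAAGGGCCGAGCGCAGAAGTGGTCCTGCAACTTTATCCGCCTCCATCCAGTCTATTAATTGTTGCC
GGGAAGCTAGAGTAAGTAGTTCGCCAGTTAATAGTTTGCGCAACGTTGTTGCCATTGCTACAGGCATCGT
GGTGTCACGCTCGTCGTTTGGTATGGCTTCATTCAGCTCCGGTTCCCAACGATCAAGGCGAGTTACATGA
TCCCCCATGTTGTGCAAAAAAGCGGTTAGCTCCTTCGGTCCTCCGATCGTTGTCAGAAGTAAGTTGGCCG
CAGTGTTATCACTCATGGTTATGGCAGCACTGCATAATTCTCTTACTGTCATGCCATCCGTAAGATGCTT
TTCTGTGACTGGTG
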