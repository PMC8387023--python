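site_label	primer_name_fwd	primer_name_rev	seq_fwd	seq_rev
200	AWM107	AWM109	CACTGCACCAAGGTAACACTC	GAAGTCAGAGCTGGAGAATCCG
500	AWM111	AWM112	CCCTACTTCAGCGCCATTCG	TAACGGAAGCACCGAATCGT
1000	AWM113	AWM115	CTCGTTGTGACGCCAATCAG	ACATTGAGCCTACGCATCTGT
1500	AWM78	AWM79	ACTACTGTCACTTCTGAGGGTTC	CAGAGGGATGCGTAGTCGTG
2000	AWM116	AWM117	CGGGGGAAGGAACTCTTGC	AGGGGTCGTCAAGCAGAGAT
control	AWM84	AWM85	CTCTGCTTGACGACCCCTTG	TGTCCGTCCGAGAGCGATA
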