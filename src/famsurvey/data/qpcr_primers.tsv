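gene	direction	sequence	anneal_temp_c	gc_percent	amplicon_bp
CteZFP28	F	TCAACAAGTGCGAGAAAACG	60.03	45	222
CteZFP28	R	ATTTGAGCTCCCATTGATGC	60.04	45	222
CteZFP43	F	TTCTTCATGGGACCCACTTC	59.9	50	236
CteZFP43	R	CCGGTGTTGGAAGCAGTAGT	60.17	55	236
CteZFP95	F	ACCAACATCAGCAGCACAAG	59.9	50	207
CteZFP95	R	GCGACACGAGAAATGAGTGA	59.99	50	207
CteZFP66	F	TTTGTGGGAGGAAGTTTTGG	59.94	45	226
CteZFP66	R	CGCCCTCTTTAACTCGTCTG	60.01	55	226
CteZFP85	F	AGTCGGACCGATATGTTTGC	59.96	50	245
CteZFP85	R	CCCATTGTTTGTGATTGCTG	59.96	45	245
CteZFP88	F	GACCAGCATCACCATTTCCT	59.93	50	224
CteZFP88	R	TTCCTCCCATTGTCGAAGAC	60.05	50	224
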