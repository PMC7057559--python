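assay_id	arm	primer_role	sequence
SWK5282	1RS	F	gaaggtgaccaagttcatgctGAGCTGATTTCCATGTA
SWK5282	1RS	H	gaaggtcggagtcaacggattGAGCTGATTTCCATGTC
SWK5282	1RS	C	TACCAAGTCCTGAACCA
SWK23822	1RL	F	gaaggtgaccaagttcatgctTATGGGAATTTATGGCCGCA
SWK23822	1RL	H	gaaggtcggagtcaacggattTATGGGAATTTATGGCCGCG
SWK23822	1RL	C	CCCGGAAAAGCTCCTTTT
SWK621	2RS	F	gaaggtgaccaagttcatgctGAGGAAGCTCCATCAATCTG
SWK621	2RS	H	gaaggtcggagtcaacggattGAGGAAGCTCCATCAATCTT
SWK621	2RS	C	CACCGAATCAATCATGCAAC
SWK252224	2RL	F	gaaggtgaccaagttcatgctTCAACACCAAGAGAAGGGAAC
SWK252224	2RL	H	gaaggtcggagtcaacggattTCAACACCAAGAGAAGGGAAA
SWK252224	2RL	C	CAGATGCATGTAGGTAGCGC
SWK28002	3RS	F	gaaggtgaccaagttcatgctCGGACAATGCACGATCGA
SWK28002	3RS	H	gaaggtcggagtcaacggattCGGACAATGCACGATCGG
SWK28002	3RS	C	CGCACGCACATCAACACG
SWK15063	3RL	F	gaaggtgaccaagttcatgctCGAAAGTATGGGCTGCATTTT
SWK15063	3RL	H	gaaggtcggagtcaacggattCGAAAGTATGGGCTGCATTTC
SWK15063	3RL	C	CCGACCCGTTCAGCCATT
SWK30487	4RS	F	gaaggtgaccaagttcatgctGGGTCGAGGTAGGTGAGG
SWK30487	4RS	H	gaaggtcggagtcaacggattGGGTCGAGGTAGGTGAGC
SWK30487	4RS	C	GCTGACGGCACAATCAAC
SWK61253	4RL	F	gaaggtgaccaagttcatgctTGAAGTACTCAGCATTCAGC
SWK61253	4RL	H	gaaggtcggagtcaacggattTGAAGTACTCAGCATTCAGT
SWK61253	4RL	C	GTTCTCTTGTTCACACTCCAGT
SWK190654	5RS	F	gaaggtgaccaagttcatgctAGGCCAAGAGAAGAGTGAAGAC
SWK190654	5RS	H	gaaggtcggagtcaacggattAGGCCAAGAGAAGAGTGAAGAT
SWK190654	5RS	C	TAACTACCGGCTGCCCTTTT
SWK37355	5RL	F	gaaggtgaccaagttcatgctTTCTGGTCCTAACGCTGAA
SWK37355	5RL	H	gaaggtcggagtcaacggattTTCTGGTCCTAACGCTGAG
SWK37355	5RL	C	CTGCATGCAATTCAAGACAGA
SWK38534	6RS	F	gaaggtgaccaagttcatgctTGAATCTCAACCATGCCCTT
SWK38534	6RS	H	gaaggtcggagtcaacggattTGAATCTCAACCATGCCCTC
SWK38534	6RS	C	CCTTGACTGTGTGGCCGATT
SWK26615	6RL	F	gaaggtgaccaagttcatgctCACTTTAACTTGGCGTTGGAG
SWK26615	6RL	H	gaaggtcggagtcaacggattCACTTTAACTTGGCGTTGGAC
SWK26615	6RL	C	CTGAACTGGCCATTTGCA
SWK31799	7RS	F	gaaggtgaccaagttcatgctACCTGAATATTGGGCGCA
SWK31799	7RS	H	gaaggtcggagtcaacggattACCTGAATATTGGGCGCC
SWK31799	7RS	C	TCACAGATCAACCTAGCCTCC
SWK13002	7RL	F	gaaggtgaccaagttcatgctATGCTTCTGCTGGTCTCTT
SWK13002	7RL	H	gaaggtcggagtcaacggattATGCTTCTGCTGGTCTCTC
SWK13002	7RL	C	CCAATACAGGAGTAGATCGAC
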