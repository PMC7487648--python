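name	sequence	purpose
7SK_F1	GACATCTGTCACCCCATTGA	RT-PCR
7SK_R1	TCCTCTATTCGGGGAAGGTC	RT-PCR
Tug1_F1	CGGAGGAGCCATCTTGTCTTGTC	RT-PCR
Tug1_R1	GCTTCCAATTCCATACACACACTG	RT-PCR
Tug1_F2	CTCTGGAGGTGGACGTTTTGT	RT-PCR
Tug1_R2	GTGAGTCGTGTCTCTCTTTTCTC	RT-PCR
Tug1_5190-5166TD_Forward	TGACTGGCCCAGAAGTTGTAAG	genotyping
Tug1_5190-5166TD_Reverse	GCAAGCAGGTCTGTGAGACTATTC	genotyping
lacZ_5_Forward	TTGAAAATGGTCTGCTGCTG	genotyping
lacZ_5_Reverse	TATTGGCTTCATCCACCACA	genotyping
Ychr_Forward	TCTTAAACTCTGAAGAAGAGAC	genotyping
Ychr_Reverse	GTCTTGCCTGTATGTGATGG	genotyping
Tug1_MluI_cDNA_Fwd	gagaacgcgtTTTTTTTTTTTTTTTTTTTTTTTTTTTTGGGGGGGTTTTTTGTTTTGTTTTTTAAATTGAAGGCTAAAGTTTTTGAAAAAACTTTGTTGGACTCTGGCTGG	cloning
Tug1_EcoRV_cDNA_Rev	gagagatatcAACTCAAAGTAACTTAAACAAAAAGGG	cloning
LNCX	AGCTCGTTTAGTGAACCGTCAGATC	sequencing
TUG1_76	TTTAAATTGAAGGCTAAAGTTTTTGAA	sequencing
TUG1_266	GGCCATTATCCAGCAAACAC	sequencing
TUG1_755	ACTCCAGGCTCCCAGATTTT	sequencing
TUG1_1254	TCTTCAAGCCAAATAACTGAAGC	sequencing
TUG1_1741	AGAACCTACATGCATTTTGTGAA	sequencing
TUG1_2268	ATGCCTCCTTAAGGCCATCT	sequencing
TUG1_2754	TGTCAACCTGTTTGCTGGAA	sequencing
TUG1_3267	TTGCAAATTCACTTTTCTATTACCTC	sequencing
TUG1_3746	CCCAACTGGCCCTTTAAGAT	sequencing
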