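human_region	gene	human_chrom	fish_chrom
4q	DCUN1D4	4	20
4q	LRRC66	4	20
4q	SGCB	4	20
4q	SPATA18	4	20
4q	USP46	4	20
4q	RASL11B	4	20
4q	SCFD2	4	20
4q	FIP1L1	4	20
4q	LNX1	4	20
4q	GSX2	4	20
4q	PDGFRA	4	20
4q	KIT	4	20
4q	KDR	4	20
4q	SRD5A3	4	20
4q	TMEM165	4	20
4q	CLOCK	4	20
4q	NMU	4	20
4q	EXOC1	4	20
4q	CEP135	4	20
4q	KIAA1211	4	20
4q	AASDH	4	20
4q	PPAT	4	20
4q	PAICS	4	20
12q region #1	CNTN1	12	4
12q region #1	PDZRN4	12	4
12q region #1	GXYLT1	12	4
12q region #1	YAF2	12	4
12q region #1	ZCRB1	12	4
12q region #2	MDM1	12	4
12q region #2	NUP107	12	4
12q region #2	SLC35E3	12	4
12q region #2	MDM2	12	4
12q region #2	CPM	12	4
14q region #2	HIF1A	14	20
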