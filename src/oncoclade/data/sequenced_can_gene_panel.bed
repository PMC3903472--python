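# sequencing-derived candidate cancer (CAN) gene panel (toy coordinates on the simplified genome)
# columns: chrom  start  end  gene
chr1	1000000	1050000	LGR6
chr3	1000000	1050000	TGFBR2
chr3	1500000	1550000	P2RY14
chr3	2000000	2050000	CHL1
chr4	1000000	1050000	ADAM29
chr4	1500000	1550000	FBXW7
chr6	1000000	1050000	SLC29A1
chr6	1500000	1550000	HIST1H1B
chr6	2000000	2050000	PHIP
chr6	2500000	2550000	SYNE1
chr6	3000000	3050000	CD109
chr8	1000000	1050000	CSMD3
chr8	1500000	1550000	RUNX1T1
chr9	1000000	1050000	PTPRD
chr10	1000000	1050000	ERCC6
chr10	1500000	1550000	RET
chr11	1000000	1050000	CD248
chr12	1000000	1050000	P2RX7
chr12	1500000	1550000	KRAS
chr13	1000000	1050000	LMO7
chr14	1000000	1050000	PRKD1
chr14	1500000	1550000	EVL
chr16	1000000	1050000	MMP2
chr16	1500000	1550000	GALNS
chr17	1000000	1050000	NF1
chr17	1500000	1550000	TP53
chr18	1000000	1050000	SMAD4
chr18	1500000	1550000	SMAD2
chr20	1000000	1050000	ERGIC3
chr20	1500000	1550000	GNAS
chr20	2000000	2050000	SFRS6
chrX	1000000	1050000	TBX22
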