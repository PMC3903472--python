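# oncogene / tumor-suppressor panel (toy coordinates on the simplified genome)
# columns: chrom  start  end  gene
chr3	1000000	1050000	RAF1
chr8	1000000	1050000	E2F5
chr8	1500000	1550000	EXT1
chr11	1000000	1050000	LRRC32
chr11	1500000	1550000	ATM
chr11	2000000	2050000	INS
chr18	1000000	1050000	DCC
chrX	1000000	1050000	KAL1
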