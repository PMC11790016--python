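##gff-version 3
chr3	synthetic	TSS	23010501	23010501	.	+	.	ID=UBE2E2_TSS
chr3	synthetic	exon	23010501	23012000	.	+	.	ID=UBE2E2_exon1
chr3	synthetic	TSS	23040501	23040501	.	-	.	ID=UBE2E1_TSS
chr3	synthetic	exon	23039000	23040501	.	-	.	ID=UBE2E1_exon1
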