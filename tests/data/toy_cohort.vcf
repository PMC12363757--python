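##fileformat=VCFv4.2
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD PHRED deleteriousness score">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class: stop_gain|missense|splice_altering|synonymous|other">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=4>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	NMC1	NMC2	L2PD1	L2PD2	IDPD1	CTRL1
4	843508	rs1134921	C	T	.	.	CSQ_CLASS=missense;GENE=GAK;CADD=30	GT	1/1	0/0	0/0	0/0	0/0	0/0
1	1100	.	A	G	.	.	CSQ_CLASS=missense;GENE=ABC1;CADD=28	GT	0/1	0/0	0/1	0/0	0/0	0/0
1	1200	.	C	A	.	.	CSQ_CLASS=stop_gain;GENE=ABC1;CADD=35	GT	0/1	0/0	0/0	0/0	0/0	0/0
1	1300	.	G	T	.	.	CSQ_CLASS=splice_altering;GENE=DEF1;CADD=26	GT	0/0	1/1	0/0	0/0	0/0	0/1
1	1400	.	T	C	.	.	CSQ_CLASS=missense;GENE=GHI1;CADD=27	GT	0/1	0/0	0/0	0/0	0/0	0/0
1	1500	.	A	T	.	.	CSQ_CLASS=stop_gain;GENE=JKL1;CADD=40	GT	0/0	0/1	0/0	0/0	0/0	0/0
1	1600	.	G	C	.	.	CSQ_CLASS=missense;GENE=MNO1;CADD=25	GT	1/1	0/0	0/0	0/0	0/0	0/0
1	1700	.	C	G	.	.	CSQ_CLASS=missense;GENE=PQR1	GT	0/1	0/0	0/0	0/0	0/0	0/0
1	1800	.	T	A	.	.	CSQ_CLASS=splice_altering;GENE=STU1;CADD=10	GT	0/0	0/1	0/0	0/0	0/0	0/0
1	1900	.	A	C	.	.	CSQ_CLASS=synonymous;GENE=XAA1;CADD=30	GT	0/1	0/0	0/0	0/0	0/0	0/0
1	2000	.	C	T	.	.	CSQ_CLASS=synonymous;GENE=XAB1;CADD=30	GT	0/0	1/1	0/0	0/0	0/0	0/0
1	2100	.	G	A	.	.	CSQ_CLASS=synonymous;GENE=XAC1;CADD=12	GT	0/1	0/0	0/0	0/0	0/0	0/0
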