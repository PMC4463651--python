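serial	length	transcript_id	intron_number	total_introns	region	in_second_db	protein_category	spliced_hits	aligned_hits	rtpcr	rnaseq	indiv_seq	gene_id	gene_symbol
1	37	HIT000059291	1	3	CDS	Yes	I	1	2	Expressed	No	Yes	HIX0029777	AQP12A
2	41	HIT000276161	4	4	CDS	Yes	II	1	23	Expressed	No	RM	HIX0001032	ENSA
3	43	HIT000008845	6	14	CDS	Yes	I	1	4	Spliced	Yes	No	HIX0013170	ESRP2
4	47	HIT000325704	2	15	CDS	Yes	II	1	1	No-Exp	No	Yes	HIX0003317	IFRD2
5	49	HIT000009363	12	13	CDS	Yes	I	3	11	Spliced	Yes	No	HIX0023123	NDOR1
6	50	HIT000084762	8	10	CDS	Yes	III	1	13	Expressed	No	No	HIX0022245	SAMD14
7	54	HIT000325704	3	15	CDS	Yes	II	1	1	Expressed	No	Yes	HIX0003317	IFRD2
8	54	HIT000333308	1	2	CDS	No	VII	1	1	Expressed	No	No	HIX0059400	HSP90B2P
9	55	HIT000278575	1	5	CDS	No	IV	1	7	Expressed	No	RM	HIX0006057	AKIRIN2
10	56	HIT000192494	7	13	CDS	Yes	I	9	10	Spliced	Yes	Yes	HIX0005482	HNRNPH1
11	61	HIT000302202	1	13	UTR5	Yes	I	1	15	Expressed	No	RM	HIX0001133	MSTO1
12	62	HIT000279220	1	7	CDS	Yes	I	9	11	Spliced	Yes	Yes	HIX0027515	SIGLEC6
13	62	HIT000333305	1	2	CDS	Yes	II	1	1	Expressed	No	No	HIX0202199	HSP90AB4P
14	62	HIT000495960	1	6	CDS	Yes	II	5	5	Spliced	Yes	No	HIX0202884	SIGLECP3
15	63	HIT000191419	3	4	CDS	Yes	I	3	3	n/a	Yes	No	HIX0079411	PRH1
16	63	HIT000091849	1	2	UTR5	Yes	VI	1	1	Expressed	No	No	HIX0036362	-
17	65	HIT000324311	10	28	CDS	Yes	II	1	1	Spliced	Yes	Yes	HIX0003640	PLXNA1
18	65	HIT000058074	1	20	CDS	Yes	I	1	4	No-PCR	Yes	Yes	HIX0034231	RECQL4
19	65	HIT000052133	11	13	CDS	Yes	IV	2	2	No-PCR	Yes	No	HIX0026183	C11orf35
20	65	HIT000082518	3	11	CDS	Yes	I	1	9	Spliced	Yes	No	HIX0202311	PDIA2
21	65	HIT000252921	4	4	CDS	Yes	I	6	8	Spliced	Yes	UC	HIX0028549	TNFRSF18
22	65	HIT000058190	7	26	CDS	Yes	I	4	4	Spliced	Yes	Yes	HIX0039022	ADAM11
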