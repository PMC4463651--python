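serial	length	region	in_intron_stop	ptc_position
1	37	CDS	no	upstream_far
2	41	CDS	no	downstream_of_last_junction
3	43	CDS	no	upstream_far
4	47	CDS	no	upstream_far
5	49	CDS	no	downstream_of_last_junction
6	50	CDS	no	upstream_far
7	54	CDS	no	no_ptc
8	54	CDS	yes	upstream_far
9	55	CDS	no	upstream_far
10	56	CDS	no	upstream_far
11	61	UTR5	no	no_ptc
12	62	CDS	no	upstream_far
13	62	CDS	no	upstream_far
14	62	CDS	no	upstream_far
15	63	CDS	no	no_ptc
16	63	UTR5	no	no_ptc
17	65	CDS	no	upstream_far
18	65	CDS	no	upstream_far
19	65	CDS	no	upstream_far
20	65	CDS	no	upstream_far
21	65	CDS	no	no_ptc
22	65	CDS	no	upstream_far
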