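gene	position	ref	alt	kind	ci	case_carriers	control_carriers	known	pair_printed	trna_position_printed	location_printed	reported_tier
MT-TQ	4373	T	C	substitution	100	1	0	N	A-U↓	28	Anticodon stem	putative
MT-TM	4452	T	C	substitution	100	1	0	Y		55	T-loop	putative
MT-TW	5558	A	G	substitution	100	2	0	Y	A-U↓	49	T-stem	putative
MT-TA	5587	T	C	substitution	100	2	0	Y		73	ACC terminus	putative
MT-TA	5595	G	A	substitution	100	1	0	N	C-G↓	65	T-stem	putative
MT-TC	5774	T	C	substitution	93	1	0	Y		59	T-loop	putative
MT-TC	5794	T	C	substitution	86	1	0	N		38	Anticodon loop	putative
MT-TC	5819	T	C	substitution	100	1	0	N		8	D-A junction	putative
MT-TS1	7502	C	T	substitution	86	1	0	Y		14	DHU-loop	putative
MT-TG	10055	A	G	substitution	100	2	0	N	A-U↓	70	ACC-stem	putative
MT-TH	12141	A	G	substitution	82	1	0	N	A-U↓	4	ACC-stem	putative
MT-TL2	12279	A	G	substitution	100	2	0	N		14	DHU-loop	putative
MT-TE	14692	A	G	substitution	88	1	0	N		55	T-loop	putative
MT-TT	15910	C	T	substitution	100	1	0	N	C-G↓	25	DHU-stem	putative
MT-TT	15948	A	G	substitution	82	1	0	N	A-U↓	68	ACC-stem	putative
MT-TT	15950	G	A	substitution	100	1	0	N	G-C↓	70	ACC-stem	putative
MT-TT	15952	C	T	substitution	93	2	0	N	C-G↓	72	ACC-stem	putative
MT-TP	15992	A	G	substitution	100	3	0	N		34	Anticodon loop	putative
MT-TF	593	T	C	substitution	29	2	2	Y		17	D-loop	other
MT-TF	636	A	G	substitution	43	1	0	N		62	T-loop	other
MT-TV	1607	T	C	substitution	59	1	0	N	C-G↑	6	ACC-stem	other
MT-TV	1664	G	A	substitution	29	1	1	Y	A-U↑	67	ACC-stem	other
MT-TL1	3290	T	C	substitution	32	2	2	Y		59	T-loop	other
MT-TQ	4363	T	C	substitution	79	1	3	Y		38	AC loop	other
MT-TQ	4369	A	G	substitution	59	1	0	N		32	Anticodon loop	other
MT-TQ	4385	A	G	substitution	68	1	1	N		16	D-loop	other
MT-TQ	4386	T	C	substitution	46	7	13	Y		15	D-loop	other
MT-TQ	4394	C	T	substitution	44	5	2	Y		7	ACC-stem	other
MT-TW	5567	T	C	substitution	65	1	0	Y	U-A↓	61	T-stem	other
MT-TA	5601	C	T	substitution	59	10	8	Y		59	T-loop	other
MT-TA	5628	T	C	substitution	93	2	3	Y	U-A↓	31	Anticodon stem	other
MT-TC	5773	G	A	substitution	24	1	2	Y		61	T-loop	other
MT-TC	5783	G	A	substitution	100	2	1	Y	G-C↓	50	T-stem	other
MT-TC	5786	T	C	substitution	50	1	0	Y		46	Variable loop	other
MT-TC	5814	T	C	substitution	85	2	1	Y	A-U↓	13	D-stem	other
MT-TC	5821	G	A	substitution	65	13	10	Y	G-C↓	6	ACC-stem	other
MT-TC	5823	A	G	substitution	29	2	0	Y	G-C↑	4	ACC-stem	other
MT-TY	5836	A	G	substitution	83	1	2	Y	G-C↑	63	T-stem	other
MT-TY	5843	A	G	substitution	88	1	1	Y		54	T-loop	other
MT-TY	5878	T	-	deletion	64	2	0	N		14	DHU-loop	other
MT-TS1	7492	C	T	substitution	68	1	1	Y	U-A↑	27a	D-A junction	other
MT-TD	7572	T	C	substitution	29	1	2	N		60	T-loop	other
MT-TK	8343	A	G	substitution	41	1	4	Y		54	T-loop	other
MT-TG	9992	C	T	substitution	49	1	1	N	C-G↓	2	ACC-stem	other
MT-TG	10007	T	C	substitution	49	1	0	Y		19	D-loop	other
MT-TG	10031	T	C	substitution	51	7	6	Y		44	Variable loop	other
MT-TR	10410	T	C	substitution	12	2	4	Y		6	ACC-stem	other
MT-TR	10411	A	G	substitution	41	1	0	Y	A-U↓	7	ACC-stem	other
MT-TR	10454	T	C	substitution	56	3	4	Y		55	T-loop	other
MT-TR	10463	T	C	substitution	94	1	1	Y		67	ACC-stem	other
MT-TH	12153	C	T	substitution	59	1	1	Y		16	D-loop	other
MT-TH	12172	A	G	substitution	93	3	2	Y		38	AC loop	other
MT-TH	12190	A	G	substitution	79	1	1	N		57	T-loop	other
MT-TH	12192	G	A	substitution	12	3	1	N		59	T-loop	other
MT-TS2	12216	C	T	substitution	39	1	0	N		10	D-loop	other
MT-TS2	12231	C	T	substitution	63	1	0	N	A-U↑	39	Anticodon stem	other
MT-TL2	12280	A	G	substitution	59	1	1	Y		15	D-loop	other
MT-TE	14687	A	G	substitution	93	1	1	Y		60	T-loop	other
MT-TE	14693	A	G	substitution	98	10	7	Y		98	T-loop	other
MT-TE	14696	A	G	substitution	93	1	1	Y	G-C↑	51	T-stem	other
MT-TE	14727	T	C	substitution	64	1	1	Y		16	DHU-loop	other
MT-TT	15889	T	C	substitution	41	2	0	Y	U-A↓	2	ACC-stem	other
MT-TT	15900	T	C	substitution	73	1	1	Y	U-A↓	13	D-stem	other
MT-TT	15924	A	G	substitution	93	9	7	Y	A-U↓	39	ACC stem	other
MT-TT	15927	G	A	substitution	49	8	16	Y	G-C↓	42	ACC stem	other
MT-TT	15928	G	A	substitution	76	2	2	Y	G-C↓	43	ACC stem	other
MT-TT	15930	G	A	substitution	22	4	15	Y		45	Variable loop	other
MT-TT	15932	T	C	substitution	64	3	0	Y		47	T-loop	other
MT-TT	15937	A	G	substitution	50	1	0	Y		53	T-loop	other
MT-TT	15940	T	C	substitution	24	4	3	Y		59	T-loop	other
MT-TT	15951	A	G	substitution	68	1	4	Y	A-U↓	71	ACC-stem	other
MT-TP	15968	T	C	substitution	27	2	2	Y	U-A↓	61	T-stem	other
MT-TP	16000	G	T	substitution	19	1	1	Y	A-U↑	26	D-A junction	other
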