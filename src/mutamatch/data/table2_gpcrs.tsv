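Drug	Target Gene	Chr	Gene Loci	Telomere Loci	Proximity (Mb)	A,T (%)	A+T (%)	FL Size (bp)
Siponimod	S1PR11	11	101	0	101	24,29	53	2778
Latanoprostene bunod	PTGFR	1	78	0	78	30,33	63	5429
Hycodan	OPRD or OPRD1	1	28	0	28	21,25	46	9317
Rexulti	5HT2A or HTR2A	13	46	113	67	31,32	63	5415
Trulicity	GLP1R	6	39	0	39	24,27	51	6682
Varubi	NK1R or TACR1	2	75	0	75	25,27	52	4779
Uptravi	PI2R or PTGIR	19	46	58	12	17,20	37	2078
Odomzo	SMO	7	129	159	30	17,22	39	3977
Tymlos	PTHR1 or PTH1R	3	46	0	46	20,21	41	2153
Kengreal	P2Y12 or P2RY12	3	151	197	46	34,33	67	2244
Zontivity	PAR1 or NR1I2	3	197	197	0.1	33,25	58	2232
Striverdi Respimat	ADRB2	5	148	181	33	23,28	51	2013
Adlyxin	GLP1R	6	39	0	39	24,27	51	6682
Belsomra	OX2R or HCRTR2	6	55	0	55	24,29	53	1952
Hetlioz	MTR1A or MTNR1A	4	186	189	3	19,23	42	1289
Symproic	OPRM or OPRM1	6	154	170	16	30,32	62	15,143
Northera	ADRB1-3 or ADRB1	10	114	133	19	18,24	42	3039
Parsabiv	CASR	3	122	197	75	26,27	53	10,062
Aristada	5HT1A or HTR1A	5	197	197	0.1	33,25	58	2232
Vraylar	DRD3	3	114	198	84	25,28	53	2770
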