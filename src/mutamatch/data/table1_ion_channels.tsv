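Drug	Target Gene	Chr	Gene Loci	Telomere Loci	Proximity (Mb)	A,T (%)	A+T (%)	FL Size (bp)
Amlodipine	CACNA1C	12	1.9	0	1.9	23,25	48	13,744
Pregabalin	CACNA2D1	7	82	158	76	31,33	64	7542
Sotalol	HERG (KCNH2)	7	150	158	8	16,19	35	4292
Flecainide	SCN5A	3	38	0	38	21,22	43	8516
Ziconotide	CACNA1B	9	138	138.1	0.1	21,22	43	9792
Lacosamide	SCN1A	2	166	241	75	30,32	62	13,079
Varenicline	CHRNA4	20	63	64	1	17,21	38	5583
Retigabine	KCNQ2	20	63	64	1	17,20	37	9163
Diazepam	GABRB3	15	26	101	75	28,31	59	5767
VU0456810	KCNJ6	21	37	46	9	29,31	60	19,659
Riluzole	KCNK4	11	64	135	71	14,20	34	1829
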