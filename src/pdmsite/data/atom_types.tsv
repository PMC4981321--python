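id	name	radius	description	class
1	NH1	1.65	Backbone NH	protein
2	C	1.76	Backbone C	protein
3	CH1E	1.87	Backbone CA (exc. Gly)	protein
4	O	1.40	Backbone O	protein
5	CH0	1.76	Arg CZ, Asn CG, Asp CG, Gln CD, Glu CD	protein
6	CH1S	1.87	Side chain CH1: Ile CB, Leu CG, Thr CB, Val CB	protein
7	CH2E	1.87	Tetrahedral CH2 (except CH2P, CH2G), all CB	protein
8	CH3E	1.87	Tetrahedral CH3	protein
9	CR1E	1.76	Aromatic CH (except CR1W, CRHH, CR1H)	protein
10	OH1	1.40	Alcohol OH (Ser OG, Thr OG1, Tyr OH)	protein
11	OC	1.40	Carboxyl O (Asp OD1, OD2, Glu OE1, OE2)	protein
12	OS	1.40	Side chain O: Asn OD1, Gln OE1	protein
13	CH2G	1.87	Gly CA	protein
14	CH2P	1.87	Pro CB, CG, CD	protein
15	NH1S	1.65	Side chain NH: Arg NE, His ND1, NE2, Trp NE1	protein
16	NC2	1.65	Arg NH1, NH2	protein
17	NH2	1.65	Asn ND2, Gln NE2	protein
18	CR1W	1.76	Trp CZ2, CH2	protein
19	CY2	1.76	Tyr CZ	protein
20	SC	1.85	Cys S	protein
21	CF	1.76	Phe CG	protein
22	SM	1.85	Met S	protein
23	CY	1.76	Tyr CG	protein
24	CW	1.76	Trp CD2, CE2	protein
25	CRHH	1.76	His CE1	protein
26	NH3	1.50	Lys NZ	protein
27	CR1H	1.76	His CD2	protein
28	C5	1.76	His CG	protein
29	N	1.65	Pro N	protein
30	C5W	1.76	Trp CG	protein
31	HOH	1.40	Water	water
32	C.3	1.91	sp3 carbon	ligand
33	C.2	1.91	sp2 carbon	ligand
34	C.1	1.91	sp carbon	ligand
35	C.ar	1.91	aromatic carbon	ligand
36	C.cat	1.91	carbocation used only in a guanidinium group	ligand
37	O.3	1.68	sp3 oxygen	ligand
38	O.2	1.66	sp2 oxygen	ligand
39	O.co2	1.66	oxygen in carboxylate or phosphate group	ligand
40	N.4	1.82	sp3 positively charged nitrogen	ligand
41	N.3	1.82	sp3 nitrogen	ligand
42	N.2	1.82	sp2 nitrogen	ligand
43	N.1	1.82	sp nitrogen	ligand
44	N.ar	1.82	aromatic nitrogen	ligand
45	N.pl3	1.82	trigonal planar nitrogen	ligand
46	N.am	1.82	amide nitrogen	ligand
47	P.3	2.10	sp3 phosphorous	ligand
48	S.3	2.00	sp3 sulfur	ligand
49	S.2	2.00	sp2 sulfur	ligand
50	S.O2	2.00	sulfone sulfur	ligand
51	F	1.75	F fluorine	ligand
52	Cl	1.95	Cl chlorine	ligand
53	Br	2.22	Br bromine	ligand
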