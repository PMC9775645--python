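# Nine amino-acid property scales (raw values; min-max normalised at load).
# composition: Dayhoff (1978) amino-acid composition of proteins (%)
# flexibility: Bhaskaran-Ponnuswamy (1988) average flexibility index
# hydrophobicity: Kyte-Doolittle (1982) hydropathy index
# net_charge: Klein (1984) net charge at pH 7
# partition: Fauchere-Pliska (1983) octanol-water partition (pi, logP)
# volume: Zamyatnin (1972) residue volume (A^3)
# molecular_weight: residue molecular weight (Da)
# asa_folded: Chothia (1976) residue accessible surface area in folded protein (A^2)
# asa_tripeptide: Chothia (1976) accessible surface area in extended tripeptide (A^2)
residue	composition	flexibility	hydrophobicity	net_charge	partition	volume	molecular_weight	asa_folded	asa_tripeptide
A	8.6	0.357	1.8	0	0.31	88.6	89.09	25	115
C	2.9	0.346	2.5	0	1.54	108.5	121.15	19	135
D	5.5	0.511	-3.5	-1	-0.77	111.1	133.10	50	150
E	6.0	0.497	-3.5	-1	-0.64	138.4	147.13	49	190
F	3.6	0.314	2.8	0	1.79	189.9	165.19	24	210
G	8.4	0.544	-0.4	0	0.00	60.1	75.07	23	75
H	2.0	0.323	-3.2	0	0.13	153.2	155.16	43	195
I	4.5	0.462	4.5	0	1.80	166.7	131.17	18	175
K	6.6	0.466	-3.9	1	-0.99	168.6	146.19	97	200
L	7.4	0.365	3.8	0	1.70	166.7	131.17	23	170
M	1.7	0.295	1.9	0	1.23	162.9	149.21	31	185
N	4.3	0.463	-3.5	0	-0.60	114.1	132.12	63	160
P	5.2	0.509	-1.6	0	0.72	112.7	115.13	50	145
Q	3.9	0.493	-3.5	0	-0.22	143.8	146.15	71	180
R	4.9	0.529	-4.5	1	-1.01	173.4	174.20	90	225
S	7.0	0.507	-0.8	0	-0.04	89.0	105.09	44	115
T	6.1	0.444	-0.7	0	0.26	116.1	119.12	47	140
V	6.6	0.386	4.2	0	1.22	140.0	117.15	18	155
W	1.3	0.305	-0.9	0	2.25	227.8	204.23	32	255
Y	3.4	0.420	-1.3	0	0.96	193.6	181.19	60	230
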