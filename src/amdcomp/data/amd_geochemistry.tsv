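Sample	pH	Temperature	DO	DOC	T-Fe	Fe2+	Fe3+	SO42-	Al	Pb	Zn	Cu	Cd	Cr	Mn
DBS	2.7	21.4	5.00	3.50	520	100	420	6966	168	0.19	80.1	60.36	0.40	0.11	116.7
FK	1.9	43.3	1.10	6.80	1240	210	1030	6690	53	0.23	144.5	4.35	0.25	0.39	13.7
YFS	2.7	31.8	3.80	2.90	2060	1090	980	6883	117	0.13	4.9	0.06	ND	0.21	27.7
YFP	2.5	32.6	1.00	3.90	2230	1350	880	7931	1878	0.40	80.9	0.02	0.01	0.23	145.7
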