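trait	qts	chrom	alleles	effect_type	effect	neglog10p	h2
Oleic	A1_44951529	A1	A/G	a	-0.276	17.8	2.98
Oleic	A1_85724143	A1	C/T	a	0.094	2.57	0.35
Oleic	A3_4717931	A3	C/T	a	0.139	3.99	0.76
Oleic	A3_4717931	A3	C/T	d	-0.399	8.98	3.11
Oleic	A7_2266630	A7	A/G	a	0.288	18.18	3.24
Oleic	A7_2266630	A7	A/G	d	0.357	2.27	2.48
Oleic	A12_120581335	A12	G/T	a	-0.275	14.45	2.95
Oleic	A12_120581335	A12	G/T	d	0.452	9.43	3.99
Oleic	D1_1087912	D1	C/T	d	0.478	7.04	4.46
Oleic	D1_37367501	D1	A/G	a	0.171	7.29	1.14
Oleic	D3_1889546	D3	T/C	d	1.019	8.09	20.28
Oleic	D5_24437741	D5	A/G	a	0.263	15.41	2.70
Oleic	D5_24437741	D5	A/G	d	-0.42	2.58	3.45
Oleic	D5_31125264	D5	G/A	a	-0.079	1.59	0.24
Oleic	D5_31125264	D5	G/A	d	-0.4	8.31	3.11
Oleic	D9_148268	D9	T/C	a	-0.228	9.74	2.03
Oleic	D9_45944489	D9	T/C	a	0.177		1.13
Oleic	A1_44951529&A1_85724143	A1&A1	A/G&C/T	aa	-0.186	8.45	2.69
Linoleic	A6_69314946	A6	T/G	a	-0.268	8	1.10
Linoleic	A9_23536520	A9	G/A	a	0.325	10.5	1.62
Linoleic	A12_117532394	A12	G/A	a	-0.255	8.42	0.99
Linoleic	A13_29883619	A13	T/C	a	0.388	16.99	2.30
Linoleic	A13_29883619	A13	T/C	d	-0.847	7.98	5.49
Linoleic	D4_21291786	D4	G/A	a	-0.359	15.41	1.97
Linoleic	D5_47644432	D5	G/C	d	0.47	3.67	1.69
Linoleic	D6_59379832	D6	A/C	a	-0.275	9.34	1.15
Linoleic	D6_59379832	D6	A/C	d	0.853	3.63	5.56
Linoleic	D4_21291786&D5_47644432	D4&D5	G/A&G/C	aa	-0.16	3.21	0.79
Linoleic	D4_21291786&D5_47644432	D4&D5	G/A&G/C	ad	0.505	3.95	3.89
Linoleic	D4_21291786&D5_47644432	D4&D5	G/A&G/C	dd	1.618	2.53	20.00
Palmitic	A1_61493378	A1	T/G	a	0.216	8.3	1.04
Palmitic	A1_61493378	A1	T/G	d	0.522	1.65	3.06
Palmitic	A7_642514	A7	C/T	a	-0.572	51.11	7.36
Palmitic	A11_600080	A11	A/G	a	0.293	12.82	1.93
Palmitic	A12_117532394	A12	G/A	a	0.269	12.83	1.63
Palmitic	A13_119809048	A13	G/A	a	0.258	11.54	1.50
Palmitic	A13_119809048	A13	G/A	d	1.025	6.27	11.82
Palmitic	D4_10313468	D4	A/C	a	-0.254	10.73	1.45
Palmitic	D4_10313468	D4	A/C	d	-0.944	11.1	10.02
Palmitic	D5_66975738	D5	A/G	a	-0.256	10.59	1.48
Palmitic	D6_10836500	D6	T/C	a	-0.292	14.63	1.91
Palmitic	A7_642514&D4_10313468	A7&D4	C/T&A/C	aa	-0.219	7.76	2.17
Palmitic	A7_642514&D4_10313468	A7&D4	C/T&A/C	da	0.407	2.12	3.72
Palmitic	A7_642514&D4_10313468	A7&D4	C/T&A/C	dd	1.809	5.89	36.79
Myristic	A1_35871478	A1	C/T	a	-0.014	10.62	2.54
Myristic	A1_35871478	A1	C/T	d	-0.029	2.33	5.30
Myristic	A1_54364850	A1	T/C	a	0.017	15.02	3.52
Myristic	A1_67270927	A1	T/C	a	-0.014	8.52	2.34
Myristic	A1_67270927	A1	T/C	d	-0.012	1.82	0.89
Myristic	A7_642514	A7	C/T	a	-0.021	8.61	4.70
Myristic	A7_642514	A7	C/T	d	-0.029	3.05	5.00
Myristic	A8_86207865	A8	G/A	a	-0.012	7.96	1.78
Myristic	A12_37853320	A12	G/A	a	0.006	2.03	0.46
Myristic	A12_37853320	A12	G/A	d	0.026	7.3	4.13
Myristic	A13_19834182	A13	C/T	a	0.015	9.08	2.92
Myristic	A13_19834182	A13	C/T	d	-0.026	10.99	4.25
Stearic	A4_17627308	A4	G/A	a	0.017	3.71	0.84
Stearic	A4_17627308	A4	G/A	ae1	-0.045	8.27	6.13
Stearic	A4_17627308	A4	G/A	ae2	-0.032	4.53	3.13
Stearic	A4_17627308	A4	G/A	ae3	0.071	8.95	14.79
Stearic	A11_110829220	A11	A/G	a	0.025	7.46	1.83
Stearic	D1_10742184	D1	T/A	a	-0.024	7.15	1.74
Stearic	D10_30598593	D10	T/G	ae1	-0.019	1.51	1.04
Stearic	D10_30598593	D10	T/G	ae2	-0.039	5.18	4.52
Stearic	D10_30598593	D10	T/G	ae3	0.055	9.84	9.15
Stearic	D10_30598593	D10	T/G	de3	0.035	1.54	1.89
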