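trait	qts	chrom	alleles	effect_type	effect	neglog10p	h2
Protein	A3_115443958	A3	T/A	a	1.302	69.59	5.14
Protein	A6_29542325	A6	G/A	a	0.408	8.16	0.50
Protein	A6_29542325	A6	G/A	d	-0.477	1.33	0.34
Protein	A7_1504479	A7	A/G	a	0.363	6.59	0.40
Protein	A7_1504479	A7	A/G	d	1.019	4.83	1.57
Protein	A11_27630663	A11	A/G	a	0.535	14.64	0.87
Protein	A11_115510024	A11	A/G	a	0.541	14.95	0.89
Protein	D1_616439	D1	C/T	a	-0.909	32.58	2.50
Protein	D2_383581	D2	A/C	d	-1.842	8.56	5.14
Protein	D3_35705563	D3	T/C	a	-0.418	8.83	0.53
Protein	D6_58640083	D6	G/A	a	0.323	5.36	0.32
Protein	D6_58640083	D6	G/A	d	-1.362	7.57	2.81
Protein	D8_18888997	D8	G/A	a	0.38	7.23	0.44
Protein	D8_18888997	D8	G/A	d	-0.513	1.35	0.40
Protein	A3_115443958&D2_383581	A3&D2	T/A&A/C	aa	-0.297	4.15	0.53
Protein	A3_115443958&D2_383581	A3&D2	T/A&A/C	ad	-2.579	11.98	20.16
Protein	A3_115443958&D2_383581	A3&D2	T/A&A/C	da	-0.784	4.74	1.86
Protein	A3_115443958&D2_383581	A3&D2	T/A&A/C	dd	1.516	1.94	3.48
Protein	A6_29542325&D8_18888997	A6&D8	G/A&G/A	dd	3.167	8.44	15.19
Protein	A7_1504479&D2_383581	A7&D2	A/G&A/C	aa	-0.142	1.31	0.12
Protein	A7_1504479&D2_383581	A7&D2	A/G&A/C	da	1.512	9.17	6.93
Protein	A7_1504479&D2_383581	A7&D2	A/G&A/C	dd	-2.902	3.21	2.76
Oil	A2_58832915	A2	G/A	a	0.24	2.5	0.16
Oil	A2_58832915	A2	G/A	d	-0.854	7.79	0.99
Oil	A6_124107263	A6	G/A	a	0.517	11.41	0.73
Oil	A6_124107263	A6	G/A	d	-1.277	5.81	2.22
Oil	A7_110987422	A7	A/C	a	-0.256	3.25	0.18
Oil	A9_85081637	A9	T/C	a	-0.555	13.04	0.84
Oil	A9_85081637	A9	T/C	d	0.563	1.47	0.43
Oil	A13_83121382	A13	T/C	a	0.763	24.58	1.58
Oil	A13_83121382	A13	T/C	d	-3.057	18.52	12.71
Oil	A13_83121382	A13	T/C	de2	-1.956	3.25	5.20
Oil	A13_83121382	A13	T/C	de3	1.262	1.59	2.17
Oil	D3_35705563	D3	T/C	a	0.163	1.57	0.07
Oil	D3_35705563	D3	T/C	d	-1.834	8.06	4.57
Oil	D6_54108367	D6	G/A	d	1.639	8.42	3.65
Oil	D10_18219333	D10	C/T	a	-0.98	40.02	2.61
Oil	D12_3388946	D12	A/G	a	-0.405	7.39	0.45
Oil	D12_3388946	D12	A/G	d	-0.608	1.37	0.50
Oil	D12_41865508	D12	G/A	a	0.526	12.01	0.75
Oil	D12_41865508	D12	G/A	d	0.911	2.49	1.13
Oil	A3_100487624&D10_18219333	A3&D10	G/A&C/T	aa	-1.208	44.59	7.94
Oil	A3_100487624&D10_18219333	A3&D10	G/A&C/T	da	1.718	32.67	8.03
Oil	A11_34775904&D9_37961611	A11&D9	G/A&C/T	aa	-0.565	12.61	1.74
Oil	A11_34775904&D9_37961611	A11&D9	G/A&C/T	ad	-0.608	1.48	1.00
Oil	A11_34775904&D9_37961611	A11&D9	G/A&C/T	da	0.741	1.95	1.49
Oil	A7_110987422&A13_83121382	A7&A13	A/C&T/C	aa	0.367	5.95	0.73
Oil	A7_110987422&A13_83121382	A7&A13	A/C&T/C	ad	-1.483	3.63	5.98
Oil	A7_110987422&A13_83121382	A7&A13	A/C&T/C	da	1.332	4.79	4.83
Oil	A7_110987422&A13_83121382	A7&A13	A/C&T/C	dd	2.138	3.1	6.21
Oil	A7_110987422&A13_83121382	A7&A13	A/C&T/C	ade2	-1.688	2.02	7.76
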