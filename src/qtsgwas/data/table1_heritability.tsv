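trait	h2_A	h2_D	h2_AA	h2_AD	h2_DA	h2_DD	h2_AE	h2_DE	h2_AAE	h2_ADE	h2_T
Protein	12.51	15.74	1.72	21.18	10.85	31.43					93.43
Oil	10.14	33.44	10.79	6.98	14.35	6.21		3.69		7.76	93.36
Palmitic	18.30	24.90	2.17		3.72	36.79					85.88
Linoleic	14.15	45.09	0.79	3.89		20.00	1.28	1.24			86.44
Oleic	23.13	54.99	2.69				0.92				81.73
Myristic	34.01	36.84					1.07		2.24		74.16
Stearic	19.79	23.37					25.05	3.41			71.62
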