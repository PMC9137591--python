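taxon	row	JC	JM	CC	printed_mean_bw
Alistipes	LBW	0.00	0.64	0.82	0.48
Alistipes	HBW	0.03	1.71	2.48	1.41
Alistipes	Mean(SP)	0.01	1.17	1.65
Bacteroides	LBW	0.11	19.06	42.39	20.52
Bacteroides	HBW	0.76	34.28	46.27	27.10
Bacteroides	Mean(SP)	0.43	26.67	44.33
Enterococcus	LBW	0.02	0.03	0.00	0.02
Enterococcus	HBW	0.22	0.02	0.00	0.08
Enterococcus	Mean(SP)	0.123	0.025	0.002
Ruminococcaceae UCG-010	LBW	0.00	0.09	0.19	0.09
Ruminococcaceae UCG-010	HBW	0.00	0.24	0.29	0.18
Ruminococcaceae UCG-010	Mean(SP)	0.00	0.17	0.24
Ruminococcaceae UCG-013	LBW	0.01	0.09	0.39	0.17
Ruminococcaceae UCG-013	HBW	0.01	0.06	0.18	0.08
Ruminococcaceae UCG-013	Mean(SP)	0.010	0.078	0.285
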