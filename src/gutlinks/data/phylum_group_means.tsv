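taxon	row	JC	JM	CC	printed_mean_bw
Actinobacteria	LBW	2.54	1.55	0.38	1.49
Actinobacteria	HBW	4.40	0.46	0.17	1.67
Actinobacteria	Mean(SP)	3.47	1.00	0.28
Bacteroidetes	LBW	0.38	20.83	45.25	22.15
Bacteroidetes	HBW	1.18	39.99	51.61	30.93
Bacteroidetes	Mean(SP)	0.78	30.41	48.43
Cyanobacteria	LBW	4.82	0.47	0.05	1.78
Cyanobacteria	HBW	3.76	1.47	0.06	1.76
Cyanobacteria	Mean(SP)	4.29	0.97	0.06
Deinococcus-Thermus	LBW	0.04	0.02	0.00	0.02
Deinococcus-Thermus	HBW	0.02	0.00	0.00	0.01
Deinococcus-Thermus	Mean(SP)	0.03	0.01	0.00
Epsilonbacteraeota	LBW	0.00	0.00	0.00	0.00
Epsilonbacteraeota	HBW	0.01	0.11	0.00	0.04
Epsilonbacteraeota	Mean(SP)	0.01	0.06	0.00
Firmicutes	LBW	88.16	74.76	51.77	71.57
Firmicutes	HBW	76.67	54.78	46.92	59.46
Firmicutes	Mean(SP)	82.42	64.77	49.35
Patescibacteria	LBW	0.25	0.05	0.00	0.10
Patescibacteria	HBW	4.03	0.12	0.00	1.38
Patescibacteria	Mean(SP)	2.14	0.09	0.00
Proteobacteria	LBW	3.78	2.25	2.39	2.81
Proteobacteria	HBW	9.88	2.72	0.98	4.53
Proteobacteria	Mean(SP)	6.83	2.48	1.68
Tenericutes	LBW	0.01	0.08	0.15	0.08
Tenericutes	HBW	0.05	0.34	0.25	0.21
Tenericutes	Mean(SP)	0.03	0.21	0.20
B/F-Ratio	LBW	0.00	0.32	0.89	0.40
B/F-Ratio	HBW	0.02	0.76	1.13	0.64
B/F-Ratio	Mean(SP)	0.01	0.54	1.01
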