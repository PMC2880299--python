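name	kind	n_individuals	ambiguous_genotypes	s	a_n	g_n	h_o
Sm2_Pop1	empirical_population	80	0	2	3	4	0.03
Sm2_Pop2	empirical_population	61	0	2	3	3	0.02
Sm2_Pop3	empirical_population	118	2	9	5	7	0.14
Sm2_Pop4	empirical_population	62	0	2	4	4	0.03
SmEF1a_Pop1	empirical_population	81	2	9	6	9	0.10
SmEF1a_Pop2	empirical_population	60	8	6	3	4	0.13
SmEF1a_Pop3	empirical_population	105	40	11	9	12	0.39
SmEF1a_Pop4	empirical_population	54	9	6	6	8	0.22
Uc3_Pop1	empirical_population	26	0	2	3	4	0.08
Uc3_Pop2	empirical_population	19	0	0	1	1	0.00
Uc3_Pop3	empirical_population	67	3	8	8	9	0.24
Uc3_Pop4	empirical_population	78	6	7	7	12	0.14
Uc3_Pop5	empirical_population	15	8	17	9	11	0.67
Uc180_Pop1	empirical_population	24	5	7	5	8	0.54
Uc180_Pop2	empirical_population	19	1	2	2	2	0.05
Uc180_Pop3	empirical_population	67	0	2	3	3	0.03
Uc180_Pop4	empirical_population	78	0	1	2	2	0.01
Uc180_Pop5	empirical_population	15	0	0	1	1	0.00
UcEF1a_Pop1	empirical_population	26	6	6	6	8	0.23
UcEF1a_Pop2	empirical_population	19	1	7	4	4	0.16
UcEF1a_Pop3	empirical_population	67	21	15	10	11	0.36
UcEF1a_Pop4	empirical_population	78	12	14	10	11	0.26
UcEF1a_Pop5	empirical_population	15	0	0	1	1	0.00
Sm2	empirical_locus	321	2	13	11	14	0.07
SmEF1a	empirical_locus	300	59	17	17	27	0.24
Uc3	empirical_locus	205	17	26	17	30	0.19
Uc180	empirical_locus	203	6	12	9	13	0.08
UcEF1a	empirical_locus	205	40	27	21	32	0.26
Sim01	simulated	50	5	5	6	6	0.26
Sim02	simulated	50	14	5	6	11	0.58
Sim03	simulated	50	2	5	6	9	0.66
Sim04	simulated	50	9	5	6	9	0.50
Sim05	simulated	50	6	5	6	8	0.50
Sim06	simulated	50	25	10	8	12	0.76
Sim07	simulated	50	34	10	9	17	0.90
Sim08	simulated	50	25	10	10	22	0.76
Sim09	simulated	50	38	10	9	15	0.80
Sim10	simulated	50	31	10	9	23	0.80
Sim11	simulated	50	36	15	11	17	0.82
Sim12	simulated	50	38	15	12	30	0.86
Sim13	simulated	50	31	15	10	20	0.78
Sim14	simulated	50	32	15	11	19	0.76
Sim15	simulated	50	36	15	12	23	0.80
Sim16	simulated	50	39	20	13	31	0.90
Sim17	simulated	50	30	20	16	33	0.72
Sim18	simulated	50	24	20	13	22	0.62
Sim19	simulated	50	27	20	12	21	0.62
Sim20	simulated	50	41	20	15	30	0.86
Sim21	simulated	50	40	25	19	37	0.90
Sim22	simulated	50	32	25	15	22	0.70
Sim23	simulated	50	30	25	17	32	0.72
Sim24	simulated	50	20	25	13	21	0.70
Sim25	simulated	50	35	25	18	29	0.84
Sim26	simulated	50	40	30	20	39	0.84
Sim27	simulated	50	41	30	17	36	0.90
Sim28	simulated	50	32	30	19	29	0.82
Sim29	simulated	50	40	30	21	38	0.90
Sim30	simulated	50	41	30	22	42	0.92
Sim31	simulated	50	37	35	17	35	0.88
Sim32	simulated	50	41	35	17	36	0.94
Sim33	simulated	50	41	35	16	32	0.88
Sim34	simulated	50	46	35	20	38	0.92
Sim35	simulated	50	38	35	15	28	0.80
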