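species	region	size_bp	pctA	pctG	pctT	pctC	at_content	at_skew	gc_skew
D. stuposa	whole	15721	39.98	7.5	40.38	12.14	80.36	-0.005	-0.236
A. plana lacteata	whole	15416	40.08	7.49	40.26	12.16	80.34	-0.002	-0.238
V. virilis	whole	15417	40.18	7.56	40.22	12.05	80.4	0.000	-0.229
G. minora	whole	15801	40.97	6.77	40.52	11.75	81.49	0.006	-0.269
R. prominens	whole	15343	40.25	7.8	40.82	11.13	81.07	-0.007	-0.176
O. lunifer	whole	15593	40.09	7.56	37.75	14.6	77.84	0.030	-0.318
A. ipsilon	whole	15377	40.38	7.71	40.87	11.04	81.25	-0.006	-0.178
D. stuposa	PCGs	11269	33.80	10.91	44.64	10.65	78.45	-0.138	0.012
A. plana lacteata	PCGs	11211	33.87	10.92	44.76	10.45	78.63	-0.138	0.022
V. virilis	PCGs	11203	33.14	11.16	45.43	10.27	78.57	-0.156	0.042
G. minora	PCGs	11237	34.72	10.11	44.98	10.2	79.7	-0.129	-0.004
R. prominens	PCGs	11216	33.64	10.57	46	9.8	79.64	-0.155	0.038
O. lunifer	PCGs	11266	32.47	12.08	43.26	12.19	75.73	-0.142	-0.005
A. ipsilon	PCGs	11211	34.24	10.64	45.56	9.55	79.8	-0.142	0.054
D. stuposa	AT_rich	406	43.6	2.46	48.77	5.17	92.37	-0.056	-0.355
A. plana lacteata	AT_rich	328	46.04	1.22	48.48	4.27	94.52	-0.026	-0.556
V. virilis	AT_rich	362	44.48	1.1	50.55	3.87	95.03	-0.064	-0.557
G. minora	AT_rich	449	43.21	2.67	49.44	4.68	92.65	-0.067	-0.273
R. prominens	AT_rich	342	44.15	2.34	49.42	4.09	93.57	-0.056	-0.272
O. lunifer	AT_rich	319	44.51	1.57	48.9	5.02	93.41	-0.047	-0.524
A. ipsilon	AT_rich	332	46.08	1.51	48.8	3.61	94.88	-0.029	-0.410
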