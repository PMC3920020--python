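family	root	leaf	flower	seed	high_spm_tissue
miR159	40458.60	114828.36	83771.72	31884.38
miR528	3583.11	87059.25	15639.47	70731.99
miR535	47988.38	41264.12	14482.89	7607.86
miR156	2340.83	595.61	81.66	32722.32	seed
miR166	1788.48	1918.84	3940.71	1489.36
miR162	2409.82	3217.41	1521.87	423.24
miR171	29.11	1872.34	3181.79	651.13
miR167	1683.43	3355.12	124.03	190.67
miR319	991.71	366.55	1967.85	1280.60
miR396	612.74	2577.08	235.45	108.16	leaf
miR894	1474.60	891.75	404.37	234.64
miR164	678.36	219.74	535.33	45.58
miR408	39.56	619.38	285.27	227.61
miR168	273.53	215.00	211.21	66.78
miR5139	219.22	232.77	151.62	125.79
miR529	48.88	8.00	80.77	54.74
miR172	1.72	46.86	147.52	1.15	flower
miR397	4.43	69.52	28.79	46.73
miR2950	47.16	50.86	49.07	1.04
miR394	5.82	10.59	25.73	14.87
miR398	1.19	38.72	6.79	2.02	leaf
miR160	5.95	14.51	22.45	2.19
miR165	9.59	7.26	12.31	1.61
miR858	0.33	0.07	24.09	0.12	flower
miR783	6.48	8.96	4.03	0.63
miR2911	8.14	0.52	1.34	2.25	root
miR1318	1.98	2.74	7.91	0.46
miR395	0.13	1.92	9.99	0.58	flower
miR399	0.99	5.55	0.60	2.48
miR3946	5.16	2.37	0.15	0.69
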