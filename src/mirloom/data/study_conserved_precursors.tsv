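family	precursor_id	length	position	mfe	source
miR156	PATC127202	110	59-168	-66.56	P
miR156	PATC133131	107	217-323	-57.13	P
miR156	PATC135255	107	217-323	-57.13	P
miR156	PATC147904	108	1193-1086	-67.86	P
miR156	PATC164883	107	320-214	-65.99	P
miR158	PATC050600	219	198-416	-58.22	M
miR159	PATC154123	242	321-80	-105.04	P
miR160	PATC024352	104	72-175	-52.08	P
miR160	PATC035616	100	112-13	-50.23	P
miR160	PATC069443	106	143-38	-57.97	P
miR162	PATC154721	136	1791-1656	-64.78	P
miR166	PATC143861	140	3037-2898	-63.8	P
miR167	PATC043563	90	150-61	-45.47	P
miR167	PATC151450	293	702-410	-109.64	P
miR168	PATC138003	96	100-195	-71.34	P
miR168	PATC161629	107	3-109	-61.87	P
miR168	PATC193994	75	47-121	-44.59	P
miR169	PATC114606	108	419-312	-45.4	M
miR169	PATC194844	109	45-153	-54.42	P
miR169	PATC195106	110	72-181	-54.33	P
miR171	PATC106872	118	146-29	-49	P
miR171	PATC151283	99	340-438	-50.89	P
miR171	PATC152062	105	468-364	-49.56	P
miR172	PATC181476	115	149-35	-53.38	P
miR172	PATC101490	86	102-187	-44.61	P
miR-1187	PATC134846	209	66-274	-72.48	M
miR-1187	PATC155430	82	150-231	-30.72	M
miR-1187	PATC155746	89	407-495	-36.33	M
miR-1187	PATC159725	216	389-174	-62.96	M
miR-1187	PATC160392	144	349-206	-42.85	M
miR-1187	PATC160599	124	119-242	-53.8	M
miR-1187	PATC177152	105	105-1	-36.62	M
miR-1187	PATC217328	87	180-266	-27.25	M
miR-1187	PATC218556	95	103-9	-33.69	M
miR-1281	PATC081629	204	1-204	-198.14	M
miR1432	PATC023631	89	146-58	-47.02	P
miR1530	PATC178976	119	169-51	-27.78	M
miR1533	PATC082198	130	41-170	-35	M
miR1533	PATC082683	223	1-223	-132.48	M
miR-24	PATC178264	125	128-4	-108.57	M
miR-2304	PATC106586	82	86-167	-34.34	M
miR-2345	PATC034115	69	253-185	-23.4	M
miR-2359	PATC166661	114	286-173	-56.45	M
miR2361	PATC130801	217	1659-1443	-70.66	M
miR-2445	PATC093130	125	144-268	-41.74	M
miR390	PATC042111	239	239-1	-109.49	M
miR394	PATC230021	100	91-190	-44.42	P
miR394	PATC230433	100	94-193	-44.42	P
miR396	PATC130914	101	33-133	-56.23	P
miR399	PATC158376	225	1084-860	-122.48	P
miR-3141	PATC075139	144	188-45	-123.39	M
miR-466	PATC091142	135	409-275	-44.66	M
miR-466	PATC103125	66	95-30	-41.86	M
miR-466	PATC118951	68	420-353	-27.53	M
miR-466	PATC120777	55	1-55	-27.43	M
miR-466	PATC144413	136	174-39	-35.63	M
miR-466	PATC186790	72	140-211	-13.5	M
miR-466	PATC192812	107	37-143	-34.51	M
miR-466	PATC155125	74	264-191	-48.23	M
miR-466	PATC158916	80	145-66	-34.52	M
miR-466	PATC183646	225	1-225	-79.49	M
miR-466	PATC226024	90	173-84	-38.95	M
miR-467	PATC095237	187	203-17	-118.01	M
miR-4044	PATC035708	96	339-244	-75.66	M
miR4077	PATC212682	91	39-129	-26.03	M
miR-4307	PATC113165	78	145-68	-22.02	M
miR4382	PATC172094	71	150-220	-18.12	M
miR528	PATC153398	103	13-115	-52.08	P
miR529	PATC150157	101	1265-1165	-43.22	M
miR535	PATC151754	101	672-772	-54.3	P
miR535	PATC196028	106	21-126	-62.5	P
miR-669	PATC082299	94	132-225	-39.8	M
miR-669	PATC230197	70	270-201	-12.72	M
miR845	PATC103597	164	71-234	-44.37	M
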