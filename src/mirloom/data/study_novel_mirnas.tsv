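mir_id	read_id	size	mature_sequence	precursor_id	precursor_length	mfe	targets
PA-miR1-5p	PASR10280190	21	UUUUGCUCAAGACCGCGCAAC	PATC206486	194	-83.52	PATC133864;PATC138350;PATC154853
PA-miR1-3p	PASR18220033	21	UGCGUGGUCUUGCGCAAGAUA	PATC206486	194	-83.52
PA-miR2-5p	PASR04371124	20	UGCAUAGCUUGUAAGAAGCC	PATC142657	105	-60.07
PA-miR2-3p	PASR17739734	21	UUUUCUUGCAAGUUAUGCAGC	PATC142657	105	-60.07	PATC131704;PATC129763
PA-miR3-5p	PASR11327008	21	UGCAUCAGUACUCCAAUGAGG	PATC207842	111	-92.14	PATC145358;PATC150760
PA-miR3-3p	PASR06328657	21	UCAUUGGAGUACUGUUGCAUC	PATC207842	111	-92.14
PA-miR4-5p	PASR18109326	24	UUCCAUGUAGUAGUCUUGACCGCU	PATC138134	76	-35.09
PA-miR5-5p	PASR07098857	22	UUUUACCUAAAAAUAGAACAGG	PATC121951	174	-58.56
PA-miR5-3p	PASR10145605	22	UGUUUUGUUCUUGGUUACUAGU	PATC121951	174	-58.56	PATC068360
PA-miR6-3p	PASR00230146	22	UAAUUUGGAUGAUACAAAGAGC	PATC024195	119	-68.46
PA-miR7-3p	PASR10868151	24	AGAUCACUGUGAUCUACAGUCAGG	PATC149891	141	-60.19	PATC135091;PATC153366
PA-miR8-5p	PASR04318366	21	UGAUUUUGGGGUACUAUAUGA	PATC197748	74	-48.22
PA-miR9-5p	PASR12483558	24	AUUGUCCGGACAAUAGAUGCGAUA	PATC057734	115	-63.01
PA-miR9-3p	PASR01446209	24	UUGCAUCUAUUGUCUGGACACUGG	PATC057734	115	-63.01
PA-miR10-5p	PASR07436675	24	UAAGUUAACGAGCCGAACACGAAC	PATC222425	85	-48.81
PA-miR11-3p	PASR12661840	22	UCAGGGGUACAAUUGUUUCUAG	PATC078804	178	-107.96
PA-miR12-5p	PASR03044487	22	AUUUCAAUGAUGGGAUGCCAUG	PATC151638	114	-53.53
PA-miR12-3p	PASR09253774	22	UGGCGUUCCAUCAUGGAAGUCC	PATC151638	114	-53.53
PA-miR13a-5p	PASR16899997	21	UCGUGUUCGGUUCGUCAAUGA	PATC223607	108	-66.61
PA-miR13b-5p	PASR16899997	21	UCGUGUUCGGUUCGUCAAUGA	PATC211404	109	-72.32
PA-miR14-5p	PASR18104423	24	UAGAUAACGAUUGAGAGAUUAGUG	PATC225301	85	-19.36
PA-miR14-3p	PASR16127551	22	UUAAGCUUUGAAUCAAUUUAAA	PATC225301	85	-19.36	PATC174550
PA-miR15-3p	PASR16174279	24	AAAUCCCAUGUUUAAGCUCACAUC	PATC100629	159	-71.46
PA-miR16-5p	PASR03747890	21	UCCUUACUCUCCAAAAAUGGG	PATC154123	228	-103.76	PATC135587
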