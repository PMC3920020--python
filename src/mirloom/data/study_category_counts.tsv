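category	library	total_reads	unique_reads
protein_coding	root	989288	38231
protein_coding	leaf	861761	36576
protein_coding	flower	799267	39707
protein_coding	seed	840605	38459
noncoding_est	root	4692205	131039
noncoding_est	leaf	4401161	122760
noncoding_est	flower	3862859	133855
noncoding_est	seed	4228824	120271
rRNA	root	916073	26320
rRNA	leaf	584814	23521
rRNA	flower	627592	23344
rRNA	seed	1066465	26117
tRNA	root	1531792	15873
tRNA	leaf	858608	13740
tRNA	flower	1851199	16072
tRNA	seed	4577493	19705
snRNA	root	7116	987
snRNA	leaf	6963	830
snRNA	flower	24549	1199
snRNA	seed	111365	1678
snoRNA	root	13180	1148
snoRNA	leaf	6948	961
snoRNA	flower	9133	1128
snoRNA	seed	27606	1399
miRNA	root	1583670	2376
miRNA	leaf	3506031	2661
miRNA	flower	1703039	2335
miRNA	seed	2567995	2466
other_sRNA	root	73124	2897
other_sRNA	leaf	50041	2750
other_sRNA	flower	56033	2759
other_sRNA	seed	115409	3117
unmatched	root	6403763	945604
unmatched	leaf	5318140	913921
unmatched	flower	5901112	986441
unmatched	seed	5032560	834739
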