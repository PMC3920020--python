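step	library	unique_reads	total_reads
input	root	6755739	23852494
input	leaf	6901052	24059282
input	flower	8538019	23741532
input	seed	5798159	25494472
input	total	22829317	97147780
after_adapter_removal	root	5787223	20618934
after_adapter_removal	leaf	5802483	20514477
after_adapter_removal	flower	7347504	20496815
after_adapter_removal	seed	4856499	22312078
after_adapter_removal	total	19207362	83942304
after_low_count_filter	root	1193873	15463951
after_low_count_filter	leaf	1161516	15293812
after_low_count_filter	flower	1231736	13668993
after_low_count_filter	seed	1079437	18097032
after_low_count_filter	total	1697668	62523788
after_contaminant_removal	root	1164475	15117306
after_contaminant_removal	leaf	1117720	13507134
after_contaminant_removal	flower	1206840	13408510
after_contaminant_removal	seed	1047951	17354424
after_contaminant_removal	total	1649996	59387374
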