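subject_id	family_id	role	age_months	sex	related	race	ethnicity	n_proteins	total_psms
F107_Mo	F107	mother	450.6	F	True	White	Non-Hispanic	819	6533
F107_C1	F107	child	27.6	F	True	White	Non-Hispanic	568	3949
F107_C2	F107	child	58	M	True	White	Other	464	2873
F123_Mo	F123	mother	447.1	F	True	White	Non-Hispanic	809	10370
F123_C1	F123	child	24	F	True	White	Non-Hispanic	499	3728
F123_C2	F123	child	52.4	M	True	White	Non-Hispanic	573	5078
F134_Mo	F134	mother	431.8	F	True	White	Missing	684	5445
F134_C1	F134	child	20.9	M	True	Mixed	Missing	387	2760
F134_C2	F134	child	67.6	F	True	Mixed	Missing	759	6872
F142_Mo	F142	mother	447.3	F	True	Asian	Missing	650	8370
F142_C1	F142	child	20.1	M	True	Mixed	Missing	581	6208
F142_C2	F142	child	50.6	M	True	Mixed	Missing	226	2353
F183_Mo	F183	mother	530	F	True	Asian	Non-Hispanic	1090	10527
F183_C1	F183	child	8.5	M	True	Asian	Non-Hispanic	314	2331
F183_C2	F183	child	44	M	True	Asian	Non-Hispanic	1010	8065
F218_Mo	F218	mother	504	F	True	White	Hispanic	609	4144
F218_C1	F218	child	58.5	F	True	White	Hispanic	524	3107
F218_C2	F218	child	35.2	F	True	White	Hispanic	631	4475
F271_Mo	F271	mother	402.6	F	True	White	Non-Hispanic	769	7525
F271_C1	F271	child	15.1	F	True	White	Non-Hispanic	557	7161
F271_C2	F271	child	42.5	F	True	White	Non-Hispanic	600	5615
F286_Mo	F286	mother	489.8	F	True	White	Non-Hispanic	616	9209
F286_C1	F286	child	22	M	True	White	Non-Hispanic	403	4727
F286_C2	F286	child	52.5	F	True	White	Non-Hispanic	614	6061
F346_C	F346	child	50.3	M	False	White	Missing	475	3429
F192_C	F192	child	38.1	F	False	Other	Hispanic	283	1731
F132_C	F132	child	51.4	F	False	White	Missing	272	1892
F363_C	F363	child	56.6	M	False	Mixed	Non-Hispanic	270	1914
F281_C	F281	child	53.5	M	False	Mixed	Mixed	406	3192
F173_C	F173	child	51.3	F	False	Other	Other	835	7168
F380_C	F380	child	14.8	M	False	Asian	Missing	237	1814
F159_C	F159	child	62.7	F	False	White	Non-Hispanic	485	3830
F179_C	F179	child	53	F	False	Asian	Other	494	2926
F149_C	F149	child	61.3	F	False	Mixed	Non-Hispanic	698	5733
F106_C	F106	child	56.7	F	False	Asian	Non-Hispanic	668	6390
F153_C	F153	child	57.1	M	False	Asian	Missing	275	2549
F256_C	F256	child	55.8	M	False	Mixed	Mixed	638	7016
F190_C	F190	child	31.5	F	False	Asian	Other	527	7460
F104_C	F104	child	50.2	M	False	White	Non-Hispanic	672	8084
F113_C	F113	child	17.9	F	False	White	Non-Hispanic	441	3640
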