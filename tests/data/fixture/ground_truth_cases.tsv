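caseid	primaryid_original	primaryid_final	ps_drug	n_versions
1000000	10000001	10000002	spironolactone	2
1000001	10000011	10000011	furosemide	1
1000002	10000021	10000021	tolvaptan	1
1000003	10000031	10000031	omeprazole	1
1000004	10000041	10000041	amlodipine	1
1000005	10000051	10000051	tolvaptan	1
1000006	10000061	10000061	spironolactone	1
1000007	10000071	10000071	spironolactone	1
1000008	10000081	10000081	aspirin	1
1000009	10000091	10000091	furosemide	1
1000010	10000101	10000101	furosemide	1
1000011	10000111	10000111	tolvaptan	1
1000012	10000121	10000121	metformin	1
1000013	10000131	10000131	spironolactone	1
1000014	10000141	10000142	furosemide	2
1000015	10000151	10000151	carvedilol	1
1000016	10000161	10000161	lisinopril	1
1000017	10000171	10000171	amlodipine	1
1000018	10000181	10000181	spironolactone	1
1000019	10000191	10000191	metformin	1
1000020	10000201	10000201	spironolactone	1
1000021	10000211	10000211	furosemide	1
1000022	10000221	10000221	tolvaptan	1
1000023	10000231	10000231	tolvaptan	1
1000024	10000241	10000242	spironolactone	2
1000025	10000251	10000251	aspirin	1
1000026	10000261	10000261	furosemide	1
1000027	10000271	10000271	amlodipine	1
1000028	10000281	10000282	aspirin	2
1000029	10000291	10000291	omeprazole	1
1000030	10000301	10000301	spironolactone	1
1000031	10000311	10000311	tolvaptan	1
1000032	10000321	10000321	furosemide	1
1000033	10000331	10000331	furosemide	1
1000034	10000341	10000341	furosemide	1
1000035	10000351	10000351	aspirin	1
1000036	10000361	10000361	aspirin	1
1000037	10000371	10000371	lisinopril	1
1000038	10000381	10000381	carvedilol	1
1000039	10000391	10000391	omeprazole	1
1000040	10000401	10000401	furosemide	1
1000041	10000411	10000412	spironolactone	2
1000042	10000421	10000421	omeprazole	1
1000043	10000431	10000431	furosemide	1
1000044	10000441	10000442	spironolactone	2
1000045	10000451	10000451	spironolactone	1
1000046	10000461	10000461	furosemide	1
1000047	10000471	10000471	carvedilol	1
1000048	10000481	10000481	omeprazole	1
1000049	10000491	10000491	aspirin	1
1000050	10000501	10000501	aspirin	1
1000051	10000511	10000511	amlodipine	1
1000052	10000521	10000521	spironolactone	1
1000053	10000531	10000531	omeprazole	1
1000054	10000541	10000541	omeprazole	1
1000055	10000551	10000551	spironolactone	1
1000056	10000561	10000561	furosemide	1
1000057	10000571	10000571	metformin	1
1000058	10000581	10000581	aspirin	1
1000059	10000591	10000591	aspirin	1
1000060	10000601	10000602	omeprazole	2
1000061	10000611	10000612	lisinopril	2
1000062	10000621	10000621	metformin	1
1000063	10000631	10000631	spironolactone	1
1000064	10000641	10000641	metformin	1
1000065	10000651	10000652	lisinopril	2
1000066	10000661	10000661	lisinopril	1
1000067	10000671	10000671	furosemide	1
1000068	10000681	10000681	amlodipine	1
1000069	10000691	10000691	furosemide	1
1000070	10000701	10000701	carvedilol	1
1000071	10000711	10000711	furosemide	1
1000072	10000721	10000721	tolvaptan	1
1000073	10000731	10000731	carvedilol	1
1000074	10000741	10000741	amlodipine	1
1000075	10000751	10000751	carvedilol	1
1000076	10000761	10000762	carvedilol	2
1000077	10000771	10000771	omeprazole	1
1000078	10000781	10000781	lisinopril	1
1000079	10000791	10000791	spironolactone	1
1000080	10000801	10000801	omeprazole	1
1000081	10000811	10000811	furosemide	1
1000082	10000821	10000821	spironolactone	1
1000083	10000831	10000831	aspirin	1
1000084	10000841	10000841	amlodipine	1
1000085	10000851	10000851	amlodipine	1
1000086	10000861	10000861	omeprazole	1
1000087	10000871	10000871	furosemide	1
1000088	10000881	10000881	aspirin	1
1000089	10000891	10000891	lisinopril	1
1000090	10000901	10000901	aspirin	1
1000091	10000911	10000911	omeprazole	1
1000092	10000921	10000922	furosemide	2
1000093	10000931	10000931	furosemide	1
1000094	10000941	10000941	furosemide	1
1000095	10000951	10000951	metformin	1
1000096	10000961	10000961	furosemide	1
1000097	10000971	10000971	amlodipine	1
1000098	10000981	10000981	aspirin	1
1000099	10000991	10000991	tolvaptan	1
1000100	10001001	10001002	tolvaptan	2
1000101	10001011	10001011	omeprazole	1
1000102	10001021	10001021	carvedilol	1
1000103	10001031	10001031	tolvaptan	1
1000104	10001041	10001041	spironolactone	1
1000105	10001051	10001051	omeprazole	1
1000106	10001061	10001061	furosemide	1
1000107	10001071	10001071	carvedilol	1
1000108	10001081	10001081	amlodipine	1
1000109	10001091	10001091	tolvaptan	1
1000110	10001101	10001102	furosemide	2
1000111	10001111	10001111	aspirin	1
1000112	10001121	10001121	furosemide	1
1000113	10001131	10001131	metformin	1
1000114	10001141	10001141	aspirin	1
1000115	10001151	10001151	tolvaptan	1
1000116	10001161	10001161	spironolactone	1
1000117	10001171	10001171	omeprazole	1
1000118	10001181	10001181	furosemide	1
1000119	10001191	10001191	metformin	1
1000120	10001201	10001201	metformin	1
1000121	10001211	10001211	metformin	1
1000122	10001221	10001221	amlodipine	1
1000123	10001231	10001231	furosemide	1
1000124	10001241	10001241	amlodipine	1
1000125	10001251	10001251	lisinopril	1
1000126	10001261	10001261	furosemide	1
1000127	10001271	10001271	aspirin	1
1000128	10001281	10001281	amlodipine	1
1000129	10001291	10001291	metformin	1
1000130	10001301	10001301	aspirin	1
1000131	10001311	10001311	tolvaptan	1
1000132	10001321	10001321	metformin	1
1000133	10001331	10001331	furosemide	1
1000134	10001341	10001341	metformin	1
1000135	10001351	10001351	amlodipine	1
1000136	10001361	10001361	tolvaptan	1
1000137	10001371	10001371	lisinopril	1
1000138	10001381	10001381	spironolactone	1
1000139	10001391	10001391	amlodipine	1
1000140	10001401	10001401	lisinopril	1
1000141	10001411	10001411	lisinopril	1
1000142	10001421	10001421	tolvaptan	1
1000143	10001431	10001431	metformin	1
1000144	10001441	10001441	lisinopril	1
1000145	10001451	10001451	carvedilol	1
1000146	10001461	10001461	furosemide	1
1000147	10001471	10001471	lisinopril	1
1000148	10001481	10001481	furosemide	1
1000149	10001491	10001491	amlodipine	1
1000150	10001501	10001501	spironolactone	1
1000151	10001511	10001511	tolvaptan	1
1000152	10001521	10001521	aspirin	1
1000153	10001531	10001531	lisinopril	1
1000154	10001541	10001541	amlodipine	1
1000155	10001551	10001551	omeprazole	1
1000156	10001561	10001561	carvedilol	1
1000157	10001571	10001571	omeprazole	1
1000158	10001581	10001581	omeprazole	1
1000159	10001591	10001591	spironolactone	1
1000160	10001601	10001601	amlodipine	1
1000161	10001611	10001611	tolvaptan	1
1000162	10001621	10001621	carvedilol	1
1000163	10001631	10001631	amlodipine	1
1000164	10001641	10001641	lisinopril	1
1000165	10001651	10001651	furosemide	1
1000166	10001661	10001661	spironolactone	1
1000167	10001671	10001671	spironolactone	1
1000168	10001681	10001681	furosemide	1
1000169	10001691	10001691	tolvaptan	1
1000170	10001701	10001701	carvedilol	1
1000171	10001711	10001711	lisinopril	1
1000172	10001721	10001721	carvedilol	1
1000173	10001731	10001731	tolvaptan	1
1000174	10001741	10001741	aspirin	1
1000175	10001751	10001751	amlodipine	1
1000176	10001761	10001761	furosemide	1
1000177	10001771	10001771	tolvaptan	1
1000178	10001781	10001782	tolvaptan	2
1000179	10001791	10001791	spironolactone	1
1000180	10001801	10001801	tolvaptan	1
1000181	10001811	10001811	tolvaptan	1
1000182	10001821	10001821	lisinopril	1
1000183	10001831	10001831	furosemide	1
1000184	10001841	10001841	spironolactone	1
1000185	10001851	10001851	omeprazole	1
1000186	10001861	10001861	furosemide	1
1000187	10001871	10001871	amlodipine	1
1000188	10001881	10001881	spironolactone	1
1000189	10001891	10001891	carvedilol	1
1000190	10001901	10001901	tolvaptan	1
1000191	10001911	10001911	carvedilol	1
1000192	10001921	10001921	aspirin	1
1000193	10001931	10001931	spironolactone	1
1000194	10001941	10001941	aspirin	1
1000195	10001951	10001951	aspirin	1
1000196	10001961	10001961	metformin	1
1000197	10001971	10001971	tolvaptan	1
1000198	10001981	10001981	aspirin	1
1000199	10001991	10001991	furosemide	1
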