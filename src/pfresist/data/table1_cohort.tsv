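isolate_id	patient_id	st	pf_isolate_names	pf_catalog_ids	n_genome_systems	genome_system_names
01-0440	01	1089	Pf01-0440	PfAC01	2	PfsE;Retron
01-5978	01	1089	ND		0	
01-7071	01	1089	Pf01-7071	PfAC01	2	PfsE;Retron
02-5135	02	312	Pf02-5135a;Pf02-5135b	PfAC02a;PfAC02b	4	Gabija;Kiwa;PfsE;ShosTA
02-5867	02	312	Pf02-5867a;Pf02-5867b	PfAC02a;PfAC02b	4	Gabija;Kiwa;PfsE;ShosTA
02-6433	02	312	Pf02-6433a;Pf02-6433b	PfAC02a;PfAC02b	4	Gabija;Kiwa;PfsE;ShosTA
03-0062	03	285	Pf03-0062	PfAC03	2	PfsE;TA-typeII
03-5302	03	285	Pf03-5302	PfAC03	2	PfsE;TA-typeII
03-5453	03	285	Pf03-5453	PfAC03	2	PfsE;TA-typeII
04-5265	04	274	Pf04-5265	PfAC01	2	PfsE;Retron
04-7991	04	274	Pf04-7991	PfAC01	2	PfsE;Retron
04-8869	04	274	Pf04-8869	PfAC01	2	PfsE;Retron
05-2269	05	NEW1	ND		0	
05-2840	05	NEW1	ND		0	
05-4672	05	360	Pf05-4672	PfAC05	2	PfsE;TA-typeII
06-6855	06	242	ND		0	
06-7209	06	242	ND		0	
06-9800	06	242	ND		0	
07-1155	07	279	ND		0	
07-5966	07	279	ND		0	
07-8998	07	279	ND		0	
08-1318	08	NEW2	Pf08-1318	PfAC08	2	IetAS;PfsE
08-4371	08	NEW2	Pf08-4371	PfAC08	2	IetAS;PfsE
08-5924	08	NEW2	Pf08-5924	PfAC08	2	IetAS;PfsE
09-0786	09	1109	Pf09-0786	PfAC09	2	PfsE;TA-typeII
09-3048	09	1109	Pf09-3048	PfAC09	2	PfsE;TA-typeII
09-9593	09	1109	Pf09-9593	PfAC09	2	PfsE;TA-typeII
10-6443	10	360	Pf10-6443	PfAC05	2	PfsE;TA-typeII
10-6518	10	360	Pf10-6518	PfAC05	2	PfsE;TA-typeII
10-7858	10	360	Pf10-7858	PfAC05	2	PfsE;TA-typeII
11-4349	11	198	ND		0	
11-7257	11	2475	Pf11-7257	PfAC11	2	Avs;PfsE
11-8664	11	2475	Pf11-8664	PfAC11	2	Avs;PfsE
12-0969	12	277	ND		0	
12-2742	12	277	ND		0	
12-2760	12	277	ND		0	
13-0154	13	1123	Pf13-0154	PfAC13	1	AbiEii toxin
13-1387	13	1123	Pf13-1387	PfAC13	1	AbiEii toxin
13-2748	13	1123	Pf13-2748	PfAC13	1	AbiEii toxin
14-4114	14	319	ND		0	
14-4688	14	319	ND		0	
14-5818	14	319	ND		0	
15-4963	15	412	ND		0	
15-7676	15	412	ND		0	
15-8860	15	412	ND		0	
16-0109	16	252	ND		0	
16-2856	16	252	ND		0	
16-4264	16	408	Pf16-4264	PfAC16	2	PfsE;TA-typeII
17-0755	17	274	ND		0	
17-3115	17	274	ND		0	
17-8321	17	274	ND		0	
18-6285	18	312	Pf18-6285	PfAC02a	3	Kiwa;PfsE;ShosTA
18-7126	18	312	Pf18-7126	PfAC02a	3	Kiwa;PfsE;ShosTA
18-9439	18	312	Pf18-9439	PfAC02a	3	Kiwa;PfsE;ShosTA
19-0943	19	1092	Pf19-0943	PfAC19	2	PfsE;TA-typeII
19-6618	19	1092	Pf19-6618	PfAC19	2	PfsE;TA-typeII
19-9746	19	1092	Pf19-9746	PfAC19	2	PfsE;TA-typeII
20-0447	20	1072	Pf20-0447	PfAC20	1	Cytosine methyltransferase
20-3695	20	1072	Pf20-3695	PfAC20	1	Cytosine methyltransferase
20-6028	20	1072	Pf20-6028	PfAC20	1	Cytosine methyltransferase
21-2955	21	198	ND		0	
21-4234	21	198	ND		0	
21-9889	21	198	ND		0	
22-5179	22	NEW3	ND		0	
22-5546	22	2101	ND		0	
22-5835	22	1134	ND		0	
23-2344	23	701	ND		0	
23-6966	23	CC701	ND		0	
23-9557	23	701	ND		0	
24-0501	24	274	Pf24-0501	PfAC01	2	PfsE;Retron
24-1092	24	274	Pf24-1092	PfAC01	2	PfsE;Retron
24-7416	24	274	ND		0	
25-6546	25	1072	Pf25-6546	PfAC20	1	Cytosine methyltransferase
25-7986	25	235	ND		0	
25-9260	25	1613	ND		0	
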