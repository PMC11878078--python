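pf_id	n_isolates	n_patients	st_list	genbank	attb_site	genome_size	n_cds	n_core_cds	n_accessory_cds	complete_systems	incomplete_systems
PfAC01	7	4	1089/274	OR863249	tRNA-Met	11915	19	15	4	Retron;PfsE	
PfAC02a	6	3	312	OR790968	tRNA-Met	13430	22	15	7	ShosTA;Kiwa;PfsE	
PfAC02b	3	1	312	OR790969	tRNA-Gly	13720	18	14	4	Gabija;PfsE	
PfAC03	3	1	285	OR801191	tRNA-Gly	12443	22	18	4	TA-typeII;PfsE	
PfAC05	4	3	360	OR801193	tRNA-Gly	12329	21	14	7	TA-typeII;PfsE	
PfAC08	3	1	NEW2	OR818368	tRNA-Gly	14433	20	15	5	IetAS;PfsE	
PfAC09	3	1	1109	OR818369	tRNA-Gly	10911	17	15	2	TA-typeII;PfsE	
PfAC11	2	1	2475	OR863245	tRNA-Met	12311	19	16	3	Avs;PfsE	
PfAC13	3	1	1123	OR863246	tRNA-Sec	10211	15	14	1		AbiEii toxin
PfAC16	1	1	408	OR863247	tRNA-Gly	11376	19	15	4	TA-typeII;PfsE	
PfAC19	3	1	1092	OR863248	tRNA-Gly	12922	20	15	5	TA-typeII;PfsE	
PfAC20	4	3	1072	PP058144	tRNA-Met	13600	18	12	6		Cytosine methyltransferase
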