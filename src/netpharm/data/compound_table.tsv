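mol_id	name	ob	dl	n_targets	herb
MOL000358	Beta-sitosterol	36.91	0.75	10	Radix Angelicae Sinensis|Radix Paeoniae Alba|Radix Ginseng|Radix Achyranthis Bidentatae
MOL000449	Stigmasterol	43.83	0.76	8	Radix Angelicae Sinensis|Radix Ginseng|Radix Achyranthis Bidentatae
MOL000359	Sitosterol	36.91	0.75	2	Rhizoma Ligustici|Cortex Moutan|Radix Paeoniae Alba|Radix Glycyrrhizae
MOL002157	Wallichilide	42.31	0.71	3	Rhizoma Ligustici
MOL002135	Myricanone	40.6	0.51	7	Rhizoma Ligustici
MOL002140	Perlolyrine	65.95	0.27	1	Rhizoma Ligustici
MOL001494	Mandenol	42	0.19	1	Rhizoma Ligustici
MOL001924	Paeoniflorin	53.87	0.79	2	Radix Paeoniae Alba
MOL000211	Mairin	55.38	0.78	1	Radix Paeoniae Alba|Cortex Moutan|Radix Glycyrrhizae
MOL001919	Palbinone	43.56	0.53	2	Radix Paeoniae Alba
MOL001925	Paeoniflorin	68.18	0.4	1	Radix Paeoniae Alba|Cortex Moutan
MOL000492	Cianidanol	54.83	0.24	2	Radix Paeoniae Alba|Cortex Moutan
MOL000422	Kaempferol	41.88	0.24	14	Radix Paeoniae Alba|Cortex Moutan|Radix Ginseng|Radix Achyranthis Bidentatae|Radix Glycyrrhizae
MOL007374	5-[[5-(4-Methoxyphenyl)-2-furyl]methylene]barbituric acid	43.44	0.3	1	Cortex Moutan
MOL000098	Quercetin	46.43	0.28	30	Cortex Moutan|Radix Achyranthis Bidentatae|Radix Glycyrrhizae
MOL000296	Hederagenin	36.91	0.75	7	Rhizoma Curcumae
MOL000787	Fumarine	59.26	0.83	2	Radix Ginseng
MOL005317	Deoxyharringtonine	39.27	0.81	2	Radix Ginseng
MOL005376	Panaxadiol	33.09	0.79	1	Radix Ginseng
MOL005348	Ginsenoside-Rh4	31.11	0.78	1	Radix Ginseng
MOL005399	Alexandrin	36.91	0.75	9	Radix Ginseng
MOL005384	Suchilactone	57.52	0.56	10	Radix Ginseng
MOL005344	Ginsenoside-Rh2	36.32	0.56	5	Radix Ginseng
MOL003648	Inermin	65.83	0.54	2	Radix Ginseng
MOL005321	Frutinone A	65.9	0.34	4	Radix Ginseng
MOL005356	Girinimbin	61.22	0.31	2	Radix Ginseng
MOL005308	Aposiopolamine	66.65	0.22	1	Radix Ginseng
MOL005320	Arachidonate	45.57	0.2	1	Radix Ginseng
MOL005318	Dianthramine	40.45	0.2	1	Radix Ginseng
MOL004924	(-)-Medicocarpin	40.99	0.95	1	Radix Glycyrrhizae
MOL004948	Isoglycyrol	44.7	0.84	3	Radix Glycyrrhizae
MOL005001	Gancaonin H	50.1	0.78	4	Radix Glycyrrhizae
MOL004903	Liquiritin	65.69	0.74	2	Radix Glycyrrhizae
MOL005012	Licoagroisoflavone	57.28	0.49	5	Radix Glycyrrhizae
MOL004941	(2R)-7-Hydroxy-2-(4-hydroxyphenyl)chroman-4-one	71.12	0.18	4	Radix Glycyrrhizae
MOL002844	Pinocembrin	64.72	0.18	4	Radix Glycyrrhizae
MOL000392	Formononetin	69.67	0.21	1	Radix Glycyrrhizae
MOL004328	Naringenin	59.29	0.21	2	Radix Glycyrrhizae
MOL001458	Coptisine	30.67	0.86	3	Radix Achyranthis Bidentatae
MOL003847	Inophyllum E	38.81	0.85	4	Radix Achyranthis Bidentatae
MOL002897	Epiberberine	43.09	0.78	3	Radix Achyranthis Bidentatae
MOL001454	Berberine	36.86	0.78	3	Radix Achyranthis Bidentatae
MOL012461	28-Norolean-17-en-3-ol	35.93	0.78	1	Radix Achyranthis Bidentatae
MOL004355	Spinasterol	42.98	0.76	2	Radix Achyranthis Bidentatae
MOL001006	Chondrillasterol	42.98	0.76	2	Radix Achyranthis Bidentatae
MOL002643	Delta 7-stigmastenol	37.42	0.75	1	Radix Achyranthis Bidentatae
MOL000085	Beta-daucosterol	36.91	0.75	10	Radix Achyranthis Bidentatae
MOL000785	Palmatine	64.6	0.65	4	Radix Achyranthis Bidentatae
MOL000173	Wogonin	30.68	0.23	14	Radix Achyranthis Bidentatae
MOL002714	Baicalein	33.52	0.21	9	Radix Achyranthis Bidentatae
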