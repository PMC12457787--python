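cultivar	VINE1	Gret1	Tvv1
Aki Queen	6160607	3875017	7207379
Campbell Early	5098552	3753653	6747361
Kyoho	4879087	3708825	6051474
Queen Nina	4203499	3185094	5124254
Grosz Krone	5685185	2132978	7184484
Koshu	4855077	4464518	5670723
Concord	3612348	3150112	6021484
Sunverde	4503994	4072960	7663586
Shine Muscat	4699603	4207124	5545859
Suiho	4560371	3772802	6830524
Steuben	3112210	2254087	8440093
Sekirei	4511269	4301931	5621816
Takao	4543490	5157150	6795875
Delaware	3812699	4781821	5863528
Niagara	3125354	3695896	5768240
Nagano Purple	3644660	3888890	4530257
Pione	4753325	2551471	7297611
Fujiminori	4156124	5539450	6568370
Black Beet	4064153	5093287	6872058
Portland	2568115	3385207	4997788
Muscat of Alexandria	2308302	1954233	11371555
Muscat Bailey A	2236182	2025233	2648449
Ruby Roman	1441058	1410932	1894495
Rosario Bianco	2112929	3672118	6440308
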