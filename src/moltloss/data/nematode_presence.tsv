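taxon	ecr	usp
Enoplida	1	1
Trichinellida	1	1
Plectida	1	1
Spirurina	1	1
Steinernematidae	1	1
Alloionematidae	0	0
Strongyloididae	0	0
Panagrolaimidae	1	0
Cephalobomorpha	1	0
Tylenchomorpha	0	0
Diplogastridae	1	1
Strongylida	1	0
Rhabditidae_other	1	1
Caenorhabditis	0	0
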