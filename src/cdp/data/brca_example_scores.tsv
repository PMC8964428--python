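drug	pns	cns	effect	ps_printed	pathway	ps_decimals
Lycorine	-1.96614484	1.2588	Enrichment	3.224945	Basal_Transcription_Factors	6
Podophyllotoxin	-1.8677839	1.2588	Enrichment	3.126584	Basal_Transcription_Factors	6
Cephaeline	-1.486685	1.2588	Enrichment	2.745485	Basal_Transcription_Factors	6
Cephaeline	-1.31212566	1.0742	Enrichment	2.386326	Cytosolic_Dna_Sensing_Pathway	6
Emetine	-1.292820115	1.0742	Enrichment	2.36702	Cytosolic_Dna_Sensing_Pathway	5
Thapsigargin	2.0442182667	-1.4763	Depletion	-3.52052	Arachidonic_Acid_Metabolism	5
Esculetin	1.8627699667	-1.4763	Depletion	-3.33907	Arachidonic_Acid_Metabolism	5
Demecolcine	1.7208179	-1.5188	Depletion	-3.23962	Jak_Stat_Signaling_Pathway	5
Thapsigargin	1.6467795333	-1.5188	Depletion	-3.16558	Jak_Stat_Signaling_Pathway	5
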