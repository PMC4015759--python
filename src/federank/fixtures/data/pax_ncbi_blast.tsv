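QueryUniprotProteinID	FoundSequenceID	FoundSequenceIDName	FoundSequenceSymbol	FoundSequenceDescription	FoundSequenceLength	BestAlignmentExpectation
P26367	P26367	UniProt	PAX6	Paired box protein Pax-6 isoform a	422	1.0E-180
P26367	P23759	UniProt	PAX7	Paired box protein Pax-7	505	1.3658E-76
P26367	Q02962	UniProt	PAX2	Paired box protein Pax-2	417	1.73781E-70
P26367	Q00288	UniProt	Pax8	Paired box protein Pax-8	457	3.2506E-69
P26367	Q06710	UniProt	PAX8	Paired box protein Pax-8	450	1.17479E-67
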