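ProteinID	ProteinIDName	GeneID	GeneIDName	GeneSymbol	TaxonomyName
P26367	UniProt	5080	Entrez	PAX6	Homo sapiens
P23759	UniProt	5081	Entrez	PAX7	Homo sapiens
Q02962	UniProt	5076	Entrez	PAX2	Homo sapiens
Q00288	UniProt	18510	Entrez	Pax8	Mus musculus
Q06710	UniProt	7849	Entrez	PAX8	Homo sapiens
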