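ProteinID	ProteinIDName	GeneticDisorderID	GeneticDisorderName	GeneticDisorderDescription
P26367	UniProt	OMIM:106210	Aniridia	Absence of the iris associated with PAX6 haploinsufficiency
Q02962	UniProt	OMIM:120330	Papillorenal syndrome	Optic nerve coloboma with renal disease
Q06710	UniProt	OMIM:218700	Congenital hypothyroidism	Thyroid dysgenesis associated with PAX8 mutations
P23759	UniProt	OMIM:268220	Rhabdomyosarcoma	Soft-tissue sarcoma associated with PAX7 fusion genes
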