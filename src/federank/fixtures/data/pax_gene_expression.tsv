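GeneID	GeneIDName	BiologicalCondition	RegulationType	ExperimentID	ExpressionPValue
5076	Entrez	tumor	up	E-GEOD-0001	1.0E-11
7849	Entrez	tumor	up	E-GEOD-0002	1.0E-11
5081	Entrez	tumor	up	E-GEOD-0003	0.0030
18510	Entrez	tumor	up	E-GEOD-0004	0.041
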