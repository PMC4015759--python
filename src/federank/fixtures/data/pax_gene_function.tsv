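GeneID	GeneIDName	BiologicalFunctionFeatureName	BiologicalFunctionFeatureID	BiologicalFunctionFeatureIDName	BiologicalFunctionFeatureDefinition
5076	Entrez	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
7849	Entrez	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
5081	Entrez	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
18510	Entrez	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
5080	Entrez	eye development	GO:0001654	GO	The process whose specific outcome is the progression of the eye over time
5076	Entrez	kidney development	GO:0001822	GO	The process whose specific outcome is the progression of the kidney over time
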