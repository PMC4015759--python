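ProteinID	ProteinIDName	BiologicalFunctionFeatureName	BiologicalFunctionFeatureID	BiologicalFunctionFeatureIDName	BiologicalFunctionFeatureDefinition
Q02962	UniProt	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
Q06710	UniProt	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
P23759	UniProt	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
Q00288	UniProt	regulation of apoptotic process	GO:0042981	GO	Any process that modulates the occurrence or rate of cell death by apoptotic process
P26367	UniProt	eye development	GO:0001654	GO	The process whose specific outcome is the progression of the eye over time
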