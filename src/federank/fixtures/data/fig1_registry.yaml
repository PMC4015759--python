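# Five-topic semantic resource framework: Protein, Gene, Gene Expression,
# Biological Function, Genetic Disorder, with the semantic connections
# defined at service registration time.
marts:
  - name: Protein
    attributes:
      - {name: SearchedDB, kind: text}
      - {name: QueryUniprotProteinID, kind: identifier}
      - {name: TopAlignment, kind: number}
      - {name: SubstitutionMatrix, kind: text}
      - {name: ExpectationUpper, kind: number}
      - {name: SearchFilter, kind: text}
      - {name: GapOpenCost, kind: number}
      - {name: GapExtensionCost, kind: number}
      - {name: FoundSequenceID, kind: identifier}
      - {name: FoundSequenceIDName, kind: text}
      - {name: FoundSequenceSymbol, kind: text}
      - {name: FoundSequenceDescription, kind: text}
      - {name: FoundSequenceLength, kind: number}
      - {name: BestAlignmentExpectation, kind: number}
  - name: Gene
    attributes:
      - {name: ProteinID, kind: identifier}
      - {name: ProteinIDName, kind: text}
      - {name: GeneID, kind: identifier}
      - {name: GeneIDName, kind: text}
      - {name: GeneSymbol, kind: text}
      - {name: TaxonomyName, kind: text}
  - name: Gene Expression
    attributes:
      - {name: GeneID, kind: identifier}
      - {name: GeneIDName, kind: text}
      - {name: BiologicalCondition, kind: text}
      - {name: RegulationType, kind: text}
      - {name: ExperimentID, kind: identifier}
      - {name: ExpressionPValue, kind: number}
  - name: Biological Function
    attributes:
      - {name: ProteinID, kind: identifier}
      - {name: ProteinIDName, kind: text}
      - {name: GeneID, kind: identifier}
      - {name: GeneIDName, kind: text}
      - {name: BiologicalFunctionFeatureID, kind: identifier}
      - {name: BiologicalFunctionFeatureIDName, kind: text}
      - {name: BiologicalFunctionFeatureName, kind: text}
      - {name: BiologicalFunctionFeatureDefinition, kind: text}
  - name: Genetic Disorder
    attributes:
      - {name: ProteinID, kind: identifier}
      - {name: ProteinIDName, kind: text}
      - {name: GeneticDisorderID, kind: identifier}
      - {name: GeneticDisorderName, kind: text}
      - {name: GeneticDisorderDescription, kind: text}
access_patterns:
  - name: NCBI-BLAST
    mart: Protein
    roles:
      SearchedDB: input
      QueryUniprotProteinID: input
      TopAlignment: input
      SubstitutionMatrix: input
      ExpectationUpper: input
      SearchFilter: input
      GapOpenCost: input
      GapExtensionCost: input
      FoundSequenceID: output
      FoundSequenceIDName: output
      FoundSequenceSymbol: output
      FoundSequenceDescription: output
      FoundSequenceLength: output
      BestAlignmentExpectation: output_ranked
    ranked_direction: ascending_better
  - name: GPDW_ProteinCodingGene
    mart: Gene
    roles:
      ProteinID: input
      ProteinIDName: input
      GeneID: output
      GeneIDName: output
      GeneSymbol: output
      TaxonomyName: output
  - name: ArrayExpress_GeneExpression
    mart: Gene Expression
    roles:
      GeneID: input
      GeneIDName: input
      BiologicalCondition: input
      RegulationType: input
      ExperimentID: output
      ExpressionPValue: output_ranked
    ranked_direction: ascending_better
  - name: GPDW_GeneBiologicalFunctionFeature
    mart: Biological Function
    roles:
      GeneID: input
      GeneIDName: input
      BiologicalFunctionFeatureName: input_output
      BiologicalFunctionFeatureID: output
      BiologicalFunctionFeatureIDName: output
      BiologicalFunctionFeatureDefinition: output
  - name: GPDW_BiologicalFunctionFeature
    mart: Biological Function
    roles:
      ProteinID: input
      ProteinIDName: input
      BiologicalFunctionFeatureName: input_output
      BiologicalFunctionFeatureID: output
      BiologicalFunctionFeatureIDName: output
      BiologicalFunctionFeatureDefinition: output
  - name: GPDW_ProteinGeneticDisorder
    mart: Genetic Disorder
    roles:
      ProteinID: input
      ProteinIDName: input
      GeneticDisorderID: output
      GeneticDisorderName: output
      GeneticDisorderDescription: output
interfaces:
  - name: ncbi_blast
    access_pattern: NCBI-BLAST
    adapter:
      endpoint: "table:ncbi_blast"
      supports_sorted_access: true
      supports_random_access: true
      max_k: null
  - name: gpdw_protein_coding_gene
    access_pattern: GPDW_ProteinCodingGene
    adapter:
      endpoint: "table:gpdw_protein_coding_gene"
      supports_sorted_access: true
      supports_random_access: true
      max_k: null
  - name: array_express_gene_expression
    access_pattern: ArrayExpress_GeneExpression
    adapter:
      endpoint: "table:array_express_gene_expression"
      supports_sorted_access: true
      supports_random_access: true
      max_k: null
  - name: gpdw_gene_biological_function
    access_pattern: GPDW_GeneBiologicalFunctionFeature
    adapter:
      endpoint: "table:gpdw_gene_biological_function"
      supports_sorted_access: true
      supports_random_access: true
      max_k: null
  - name: gpdw_protein_biological_function
    access_pattern: GPDW_BiologicalFunctionFeature
    adapter:
      endpoint: "table:gpdw_protein_biological_function"
      supports_sorted_access: true
      supports_random_access: true
      max_k: null
  - name: gpdw_protein_genetic_disorder
    access_pattern: GPDW_ProteinGeneticDisorder
    adapter:
      endpoint: "table:gpdw_protein_genetic_disorder"
      supports_sorted_access: true
      supports_random_access: true
      max_k: null
connections:
  - name: ProteinCodingGene
    source_mart: Protein
    target_mart: Gene
    predicate:
      - {source: FoundSequenceID, comparator: EQ, target: ProteinID}
      - {source: FoundSequenceIDName, comparator: EQ, target: ProteinIDName}
  - name: GeneExpressionOfGene
    source_mart: Gene
    target_mart: Gene Expression
    predicate:
      - {source: GeneID, comparator: EQ, target: GeneID}
      - {source: GeneIDName, comparator: EQ, target: GeneIDName}
  - name: ExistsGeneBiologicalFunctionFeature
    source_mart: Gene
    target_mart: Biological Function
    predicate:
      - {source: GeneID, comparator: EQ, target: GeneID}
      - {source: GeneIDName, comparator: EQ, target: GeneIDName}
  - name: ExistsProteinBiologicalFunctionFeature
    source_mart: Protein
    target_mart: Biological Function
    predicate:
      - {source: FoundSequenceID, comparator: EQ, target: ProteinID}
      - {source: FoundSequenceIDName, comparator: EQ, target: ProteinIDName}
  - name: ExistsProteinGeneticDisorder
    source_mart: Protein
    target_mart: Genetic Disorder
    predicate:
      - {source: FoundSequenceID, comparator: EQ, target: ProteinID}
      - {source: FoundSequenceIDName, comparator: EQ, target: ProteinIDName}
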