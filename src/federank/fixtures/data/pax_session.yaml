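# Replay of the PAX exploration: protein-similarity search for P26367,
# expansion to the coding genes, to tumor up-regulation evidence, and to
# the "regulation of apoptotic process" annotation, with TSV/JSON exports.
world: pax
options:
  k: 50
  strategy: complement
actions:
  - start:
      interface: ncbi_blast
      inputs:
        SearchedDB: UniProtKB/Swiss-Prot
        QueryUniprotProteinID: P26367
        TopAlignment: "100"
        SubstitutionMatrix: BLOSUM62
        ExpectationUpper: "10.0"
        SearchFilter: none
        GapOpenCost: "11"
        GapExtensionCost: "1"
  - expand:
      connection: ProteinCodingGene
      interface: gpdw_protein_coding_gene
  - expand:
      connection: GeneExpressionOfGene
      interface: array_express_gene_expression
      inputs:
        BiologicalCondition: tumor
        RegulationType: up
  - expand:
      connection: ExistsGeneBiologicalFunctionFeature
      interface: gpdw_gene_biological_function
      inputs:
        BiologicalFunctionFeatureName: regulation of apoptotic process
  - export:
      path: pax_results.tsv
      format: tsv
  - export:
      path: pax_results.json
      format: json
  - export_history:
      path: pax_history.json
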