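# gemqc

Validation, simulation and version-comparison toolkit for genome-scale
metabolic network reconstructions. It covers the standard evaluation
workflow for consensus-style yeast models:

- **SBML I/O** in two dialects — Level 3 + Flux Balance Constraints
  (fbc v1 and v2) and the Level 2 COBRA-Toolbox convention — preserving
  MIRIAM-style annotations (ChEBI/UniProt cross-references, PubMed
  evidence) and gene–protein–reaction (GPR) boolean trees.
- **FBA engine**: growth simulation under defined media, single-gene
  deletion screening, flux variability analysis and blocked-reaction
  detection (scipy/HiGHS).
- **Assessment**: essentiality benchmarking with full contingency
  statistics (sensitivity, specificity, PPV, NPV, MCC, geometric-mean
  accuracy) and auxotrophy classification against minimal/supplemented
  media.
- **Model diffing**: identifier-based comparison of two versions sharing
  the stable `r_####`/`s_####` id scheme, including constraint changes.
- **Fixture generator**: deterministic synthetic reconstructions with
  known ground truth (essential genes, blocked reactions, auxotrophs)
  plus independent brute-force oracles, so everything is testable
  offline.

## CLI

```sh
gemqc summarize MODEL.xml --out out/            # entity counts, PMID coverage
gemqc blocked MODEL.xml --out out/              # blocked-reaction detection
gemqc growth MODEL.xml --medium anaerobic_minimal --out out/
gemqc fva MODEL.xml --out out/
gemqc essentiality MODEL.xml essential.txt orfs.txt --medium minimal.tsv --out out/
gemqc auxotrophy MODEL.xml aux_genes.txt --minimal-medium minimal.tsv --out out/
gemqc diff OLD.xml NEW.xml --out out/
```

Media are TSV files (`reaction_id`, `lower_bound`, `upper_bound`);
`--medium` accepts either a path or a shipped preset name
(`minimal_aerobic_glucose`, `anaerobic_minimal`,
`anaerobic_sterol_supplemented`). Gene lists are one identifier per
line. Exchange reactions follow the sign convention *positive flux =
secretion, negative flux = uptake*. Exit codes: 0 success, 2 input
error, 3 infeasible precondition, 4 solver failure.

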