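# cernanet

Construction and analysis of competing endogenous RNA (ceRNA) networks from
expression profiles and miRNA–target interaction tables — as a scriptable
library and batch CLI.

Given (1) a candidate-ceRNA expression matrix, (2) a miRNA expression
matrix, (3) a miRNA→target interaction table and (4) a gene annotation
table (all plain delimited text), the pipeline:

1. **harmonizes** symbols across the four inputs (`cernanet.io_harmonize`),
2. **groups and filters** genes/samples by detected-RNA and
   expressing-sample ratio thresholds, then applies log / min–max /
   z-score transforms (`cernanet.preprocessing`),
3. computes up to five **pair measures** per candidate gene pair
   (`cernanet.pair_measures`):
   - **MS** — hypergeometric upper-tail enrichment of shared targeting
     miRNAs,
   - **PCC** — Pearson correlation,
   - **MI** / **CMI** — (conditional) mutual information on discretized
     expression, CMI conditioning on the summed expression of the pair's
     shared miRNAs,
   - **LA** — liquid association with Van der Waerden normal scores of the
     shared-miRNA expression,
4. applies strict directional **thresholds** per group pair and assembles
   the undirected network with isolated nodes retained
   (`cernanet.network_build`),
5. analyzes it: degree / betweenness / closeness / clustering / edge
   betweenness (`cernanet.topology`), Louvain modules with a
   modularity/density report and module-associated miRNAs
   (`cernanet.community`), local hypergeometric over-representation and
   Kaplan–Meier / log-rank / Cox module-biomarker survival analysis
   (`cernanet.enrichment_survival`).

A seeded synthetic-data generator with planted ceRNA triads
(`cernanet.fixtures`) makes every stage testable without downloads.

## CLI

Single entry point `cernanet` with subcommands:

```sh
# generate a synthetic dataset (4 input files + planted ground truth)
cernanet simulate --seed 0 --out data/

# check inputs and print harmonized-set sizes
cernanet validate --cerna-expr data/cerna_expr.tsv --mirna-expr data/mirna_expr.tsv \
    --interactions data/interactions.tsv --annotation data/annotation.tsv

# batch pipeline driven by a YAML config
cernanet preprocess --config config.yaml
cernanet construct  --config config.yaml          # writes edges.tsv, nodes.tsv,
                                                  # network.graphml, summary.json,
                                                  # density_*.tsv, manifest.json
cernanet topology --network out/network.graphml --out out/
cernanet modules  --network out/network.graphml --resolution 1.0 --seed 0 --out out/
cernanet enrich   --query q.txt --gmt sets.gmt --universe u.txt --out out/
cernanet survival --survival-table surv.tsv --expression expr.tsv \
    --module-genes ZNF580,RPL34 --out out/
```

Example `config.yaml`:

```yaml
inputs:
  cerna_expr: data/cerna_expr.tsv
  mirna_expr: data/mirna_expr.tsv
  interactions: data/interactions.tsv
  annotation: data/annotation.tsv
  delimiter: auto
grouping:
  attribute: biotype
  rule: {protein_coding: Coding}
  default_group: Noncoding
sample_filter:
  cerna_detect_threshold: 1.0
  mirna_detect_threshold: 1.0
  drop_lowest: [2, 2]
gene_filter:
  groups:
    Coding:    {min_expr: 1.0, min_fraction: 0.8}
    Noncoding: {min_expr: 0.5, min_fraction: 0.5}
  mirna: {min_expr: 1.0, min_fraction: 0.8}
transform:
  log: {base: 2, pseudocount: 1.0}
measures: [MS, PCC, LA]
thresholds:
  - {measure: MS,  direction: less-than,    cutoff: 0.05, group_pair: all}
  - {measure: PCC, direction: greater-than, cutoff: 0.48, group_pair: Coding|Coding}
  - {measure: PCC, direction: greater-than, cutoff: 0.46, group_pair: all}
  - {measure: LA,  direction: greater-than, cutoff: 0.3,  group_pair: all}
out: out/
seed: 0
workers: 4
```

Unknown config keys are rejected before any computation; every run writes a
`manifest.json` (config echo, package version, input checksums, seed) and a
`run.log`.

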