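# contextcore

Context-specific metabolic model extraction from discretized expression
data, with downstream comparative, statistical, regulatory-load and
network-topology analyses.

The package builds flux-consistent, context-specific models from a
genome-scale SBML reconstruction and per-gene expression z-scores:

1. **Discretization** — z-scores become trinary calls (`z <= 0 → -1`,
   `z > 5 → +1`, else `0`), optionally aggregated across samples by
   consensus fractions or ubiquity sums.
2. **GPR mapping** — gene calls propagate to reactions through Boolean
   gene–protein–reaction rules (AND = min, OR = max).
3. **Core-set construction** — expressed reactions form the core;
   expressed *transporters* are made non-penalized instead (their
   promiscuous genes would otherwise drag whole subsystems in);
   unexpressed reactions are removed.
4. **Extraction** — an LP-based consistency sweep (`fastcc`) plus a
   two-LP core-extraction algorithm with weighted penalties
   (`fastcore_extract` / `modified_fastcore`), with optional medium
   constraints and biomass forcing (two-pass scheme).
5. **Cross-validation** — leave-one-core-reaction-out rebuilds assign
   high / moderate / low confidence to retained reactions and
   multi-/single-evidence labels to exclusions.

Analyses on top: Jaccard model similarity with clustering, per-subsystem
activity and regulation scores, FBA gene knockouts (>1 % growth-decrease
essentiality), KS/permutation rank-set enrichment, exact hypergeometric
tails, transporter/pathway-entry-point classification with cofactor
filtering, and an enhancer regulatory-load pipeline (replicate-reproducible
peaks → 450 bp extension → single nearest TSS within 500 kb → top-10 % ∩
≥7-enhancer high-regulatory-load genes).

A `fixtures` module generates deterministic toy SBML models, expression
tables and replicate peak sets with known ground truth, so the whole stack
is testable offline.

## CLI

```bash
contextcore validate model.xml
contextcore fastcc model.xml --eps 1e-4 -o consistent.xml
contextcore fastcore model.xml --core core.txt [--nonpenalized np.txt --forced BIOMASS]
contextcore discretize zscores.tsv -o scores.tsv
contextcore build model.xml --expr zscores.tsv [--medium medium.txt --biomass BIOMASS --crossval] -o ctx
contextcore compare ctx1.xml ctx2.xml -o jaccard.tsv
contextcore pathways parent.xml ctx.xml -o activity.tsv
contextcore essentiality model.xml --biomass BIOMASS -o essential.tsv
contextcore entrypoints model.xml -o classes.tsv [--edges edges.tsv]
contextcore regload --replicate r1.bed --replicate r2.bed --replicate r3.bed --tss tss.tsv -o load.tsv
contextcore simulate --what model|expr|peaks --seed 1 -o fixtures/
```

`build` writes the context model as SBML, a per-reaction confidence TSV
and a provenance JSON.

## Layout

```
src/contextcore/
  model_io.py        SBML read/write, model container, GPR parser
  consistency.py     FVA, FBA, LP-7 consistency sweep + naive oracle
  fastcore.py        core extraction with non-penalized/forced sets
  expression.py      discretization, consensus, ubiquity
  gpr_mapping.py     gene→reaction score propagation
  workflow.py        orchestration, medium, cross-validation
  model_analysis.py  Jaccard, pathway scores, essentiality, statistics
  topology.py        transporters, entry points, positional enrichment
  regulatory.py      peak intersection, TSS assignment, HRL selection
  fixtures.py        deterministic toy-data generators
  cli.py             click-based CLI (`contextcore`)
tests/               pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
```
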