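# mitosig

Comparative mitogenomics toolkit for clade-level sequence signatures:
rule-based mitogenome annotation, intergenic-spacer and tRNA-loop signature
discovery, codon-aware and structure-guided alignments, p-distance clade
summaries, quartet likelihood mapping, and parsimony mapping of ecological
traits — plus a seeded synthetic-data generator that provides ground truth
for every stage.

## What it does

The package models a typical comparative study of a small moth radiation:
thirteen taxa in three ingroup clades (A, B, C) plus outgroups, each genome
represented by three mitochondrial segments (`cox1`–`cox3`, `nad5`–`nad4`,
`cob`–control region) and three nuclear genes.

| Module | Purpose |
| --- | --- |
| `synthgen` | Simulate segments under HKY/GTR+Γ along a reference tree, with injected spacer gain/loss events, tRNA-loop replacements and ecological traits; writes a full ground-truth bundle |
| `mitoannot` | Recover features from sequence alone: anticodon-anchored cloverleaf search for tRNAs, expected-length-matched start/stop rules for protein-coding genes (including truncated T/TA stops completed by polyadenylation), tRNA-delimited rRNAs, leftover intergenic spacers; GFF3 output |
| `alignkit` | Affine-gap profile alignment; codon-aware alignment of protein-coding genes (align the translation, backtranslate); structure-guided tRNA alignment that slides gaps out of stems; named concatenations with RAxML-style partition files |
| `cladedist` | p-distance matrices (pairwise or complete deletion), bootstrapped within/among-clade summaries with half-up 3-decimal rounding, neighbour joining |
| `treesignal` | Felsenstein pruning likelihood with discrete-Γ rates, quartet likelihood mapping (resolved / partly / unresolved percentages per alignment) |
| `signatures` | Group spacers by locus, minimal-degeneracy IUPAC consensus motifs, Dollo-style classification of presence patterns (ubiquitous / clade-restricted / lineage-specific), clade-diagnostic tRNA-loop motifs |
| `traitmap` | Sankoff parsimony: ancestral state sets over all most-parsimonious reconstructions, forced changes, minimum independent origins per state, annotated Newick output |
| `pipeline` / `cli` | One seeded run directory through all stages with an evaluation against the ground truth and a checksummed manifest |

## Quick start

```bash
# full synthetic run: simulate -> annotate -> align -> distances -> signal
#   -> signatures -> traits -> evaluate
mitosig run --seed 1 --run-dir results/run_seed1

# or stage by stage
mitosig simulate --seed 1 --run-dir results/run_seed1
mitosig annotate --run-dir results/run_seed1
mitosig dist --run-dir results/run_seed1
```

The same stages are scripted as numbered drivers under `analysis/`
(`01_simulate.py` … `07_evaluate.py`), each re-runnable from the run
directory on disk.

From Python:

```python
from mitosig.pipeline import PipelineRun

run = PipelineRun("results/run_seed1", seed=1)
run.run_all()
print(run.evaluate())   # boundary/anticodon/spacer recovery vs ground truth
```

## Tests

```bash
python -m pytest -q tests/
```

One test per acceptance criterion lives in `tests/test_acceptance.py`. The
real-data benchmark test fails with an explanatory message when
`data/real/` is empty — this is deliberate: it documents an input the
offline environment cannot provide, rather than silently skipping.

## Documentation

Method details — substitution models, annotation rules, alignment scoring,
quartet geometry, parsimony conventions — are in
[`docs/methods.md`](docs/methods.md).
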