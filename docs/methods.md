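# Methods

This document specifies the algorithms and conventions implemented by each
module. All coordinates are 0-based half-open on the stored forward strand;
minus-strand features are analysed on the reverse complement and mapped
back. All randomness flows from a single seed; every stage re-run with the
same inputs is byte-identical.

## Substitution models (`models`)

Reversible GTR-family models on `ACGT`, parameterised by stationary
frequencies π and six exchangeabilities; HKY is the two-exchangeability
special case, and `hky_at_rich()` is the package default (AT-rich
frequencies typical of insect mitogenomes). The rate matrix Q is scaled so
the expected substitution rate at stationarity is 1, so branch lengths are
expected substitutions per site. Transition probabilities P(t) = exp(Qt)
come from the eigendecomposition of the symmetrized matrix
B = diag(√π) · Q · diag(1/√π), cached per model.

Among-site rate variation uses the discrete-gamma approximation with four
equal-weight categories whose rates are the category-mean quantiles of a
Gamma(α, α) distribution (mean 1, so the rate scale is preserved).

## Synthetic data generation (`synthgen`)

A truth bundle simulates thirteen taxa (three ingroup clades A, B, C plus
outgroups) along a fixed reference topology. Each genome consists of three
mitochondrial segments following the standard insect gene order
(`cox1`…`cox3`; `nad5`…`nad4` on the minus strand; `cob`…control region)
plus three nuclear genes.

* **Protein-coding genes** evolve per-codon with start codons and the
  absence of internal stops preserved; template gene lengths are fixed.
  Two genes terminate in truncated stops (`T`, `TA`) completed by
  polyadenylation, flush against the downstream feature.
* **tRNAs** evolve under a structure-aware constraint: stem positions stay
  paired in the canonical cloverleaf, loops and linkers evolve at the tRNA
  rate, anticodons are frozen.
* **Spacer events** inject or delete intergenic spacers on named branches
  (e.g. an ancestral spacer deleted on the clade-A stem; clade- and
  lineage-specific insertions between `cox1` and `trnL2`). Carrier sets are
  recorded as ground truth.
* **Loop events** replace a named tRNA loop (DHU or TΨC) with a fixed motif
  on a named branch, possibly changing the tRNA length; these are the
  injected clade-diagnostic signatures.
* **Traits** paint discrete ecological states (e.g. a convergent
  morphological character present in clade BC and one clade-A lineage) onto
  the leaves.

The configuration (tree, events, traits, model) round-trips through YAML.

## Annotation (`mitoannot`)

The annotator sees only sequence plus the expected gene-order template.

* **tRNAs** — anticodon-anchored cloverleaf search: every occurrence of the
  expected anticodon inside a drift-corrected window is a candidate anchor;
  for each anchor the best-scoring geometry over a small grid (acceptor
  stem 7 bp, D stem 3–4 bp, anticodon stem 5 bp, T stem 4–5 bp, loops of
  variable length) is kept. A Watson–Crick pair scores 1, a G·T wobble 0.5.
  Anchors within 1.0 pairing unit of the best score tie; ties break by
  proximity to the anchor position implied by the template. Folds below the
  confidence threshold (80 % of pairable positions) are kept but flagged
  weak, since the window is template-anchored.
* **PCG 5′ ends** — among legitimate start codons (ATN, GTG, TTG, GTT) in
  the scan window, keep those whose ORF resolves to a 3′ end and spans at
  least half the expected length, then choose the candidate whose full gene
  span best matches the template-expected length (ties go to the most-5′
  candidate). This emulates the homology evidence a comparative annotation
  has: a bare "first start" rule is occasionally pre-empted by a legitimate
  start that mutation creates inside an upstream spacer. A per-gene overlap
  allowance lets `atp6` begin inside `atp8`.
* **PCG 3′ ends** — first in-frame stop codon; if none fits before the
  downstream same-strand feature and the in-frame remainder at the boundary
  is `T` or `TA`, a truncated stop completed by polyadenylation is
  annotated flush against the downstream feature.
* **rRNAs** — delimited by their flanking tRNAs and expected lengths: rrnL
  is right-anchored at `trnV` and extends its expected length toward
  `trnL1` (any leftover stays intergenic); rrnS runs from `trnV`. The
  AT-rich remainder of the terminal segment is the control region.
* **Spacers** — the leftover gaps between consecutive annotated features,
  recorded even when empty so presence/absence patterns are well defined.

Output: per-segment feature tables, spacer and tRNA-loop tables, GFF3.

## Alignment (`alignkit`)

Pairwise and progressive profile alignment with affine gaps (open 10,
extend 0.5; a gap run of length L costs `open + extend·(L−1)`), guide tree
by average linkage on k-mer distances. Protein scoring uses BLOSUM62,
nucleotide scoring match 5 / mismatch −4.

* **Codon-aware PCG alignment** — truncated stops are completed, sequences
  translated with the invertebrate mitochondrial code (any legitimate start
  translates to M), proteins aligned, and the alignment back-translated so
  every gap run is a whole number of codons.
* **Structure-guided tRNA alignment** — sequences are aligned against the
  canonical cloverleaf structure track; when a gap column can be slid
  without changing the sum-of-pairs score, it is moved out of stem regions
  into loops, keeping stems intact.
* **Concatenation** — named gene sets (all 13 mitochondrial PCGs, nuclear
  sets, tRNA and rRNA sets) are concatenated with RAxML-style partition
  files; PCG partitions can be split by codon position. Taxa missing a gene
  are either dropped or padded with gaps, per set definition.

## Distances and clade summaries (`cladedist`)

Uncorrected p-distances with pairwise or complete gap deletion
(`N`/gap are not comparable; pairs with no comparable sites are NaN).
Clade summaries report within-clade and among-clade mean distances with a
nonparametric bootstrap over pairs (seeded) and a standard error; means are
also reported rounded to 3 decimals with half-up rounding (`round3`), the
convention used by the packaged fixture tables. Outgroup taxa are excluded
unless explicitly included. Neighbour joining builds trees from any
distance matrix.

## Likelihood and quartet mapping (`treesignal`)

Site log-likelihoods use Felsenstein pruning over compressed site patterns
with the discrete-gamma mixture; gaps and ambiguity codes are marginalized
(an all-ones leaf partial). Partitioned data sums per-partition
log-likelihoods.

Quartet likelihood mapping draws quartets (all, or a seeded sample), and
for each quartet optimizes branch lengths for the three possible pairings
by coordinate ascent (Brent line search with cached through-partials). The
three likelihood weights classify the quartet: **resolved** when the best
weight exceeds twice the runner-up, **partly resolved** when the top two
each exceed twice the third, otherwise **unresolved**; exact 2:1 boundaries
fall to the less resolved class. The signal report gives the percentage of
resolved / partly / unresolved quartets per alignment, which sums to 100.

## Signatures (`signatures`)

Spacers are grouped per locus; carriers (taxa with a non-empty spacer) get
a minimal-degeneracy IUPAC consensus motif when their mean pairwise
identity is at least 0.6. Presence patterns are classified on the reference
tree by Dollo-style parsimony (gains penalized over losses):
**ubiquitous** (present at the root, no losses), **clade-restricted**
(gained on an internal branch, possibly with later losses), or
**lineage-specific** (gained on a terminal branch). Diagnostic tRNA-loop
motifs are clade-level IUPAC consensi (bounded degeneracy) reported only
when they match every member of the clade and no taxon outside it.

## Trait mapping (`traitmap`)

Sankoff parsimony with unit costs over arbitrary state sets; `?` is a free
(missing) observation. The reconstruction reports, per node, the set of
states that occur in at least one most-parsimonious labeling, the forced
changes (branches that change state in every labeling), and the minimum
number of independent origins of a state — counted as gain branches plus
one if the state can be present at the root. A trait state is called
convergent when its minimum origins exceed one. Annotated Newick output
embeds the per-node state sets.

## Pipeline and evaluation (`pipeline`, `cli`)

`PipelineRun` owns one run directory (`truth/`, `annotation/`,
`alignments/`, `concat/`, `distances/`, `signal/`, `signatures/`,
`traits/`, `evaluation.json`, `manifest.json`). Every stage can be re-run
from disk. `evaluate()` scores the annotation against the simulated truth:
exact PCG boundary recovery, truncated-stop recovery, tRNA detection and
boundary recovery, per-locus spacer presence-pattern recovery, diagnostic
motif false positives (by re-matching against the truth clade map), and
minimum origins per trait state. The manifest records SHA-256 checksums of
all written artifacts.
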