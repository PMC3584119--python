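"""mitosig: comparative mitogenomics of partial genome segments.

Subpackages cover the full workflow used for small multi-taxon mitogenome
studies: synthetic data generation with known truth (:mod:`~mitosig.synthgen`),
rule-based segment annotation (:mod:`~mitosig.mitoannot`), codon-aware and
structure-guided alignments plus named concatenations
(:mod:`~mitosig.alignkit`), quartet likelihood mapping and pruning
likelihoods (:mod:`~mitosig.treesignal`), p-distance clade summaries
(:mod:`~mitosig.cladedist`), spacer/loop signature discovery
(:mod:`~mitosig.signatures`), parsimony trait mapping
(:mod:`~mitosig.traitmap`) and pipeline orchestration
(:mod:`~mitosig.pipeline`).
"""

from importlib import resources as _resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a packaged data fixture (reference tree, clade table,
    printed distance matrices, trait matrix)."""
    return _resources.files("mitosig").joinpath("data", name)
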