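"""Shared fixtures: one pool of default synthetic bundles, annotated and
evaluated once per session, plus the packaged reference data."""

from __future__ import annotations

import pytest

from mitosig import data_path, pipeline

BUNDLE_SEEDS = tuple(range(20))


@pytest.fixture(scope="session")
def bundle_runs(tmp_path_factory):
    """simulate + annotate + evaluate for the 20 default synthetic bundles.

    Returns (runs, metrics): seed -> PipelineRun with truth and annotations
    in memory, and seed -> evaluation metric dict.
    """
    base = tmp_path_factory.mktemp("bundles")
    runs, metrics = {}, {}
    for seed in BUNDLE_SEEDS:
        run = pipeline.PipelineRun(base / f"seed{seed}", seed=seed)
        run.simulate()
        run.annotate()
        metrics[seed] = run.evaluate()
        runs[seed] = run
    return runs, metrics


@pytest.fixture(scope="session")
def default_run(bundle_runs):
    """One default bundle (seed 1) with truth and annotations loaded."""
    runs, _ = bundle_runs
    return runs[1]


@pytest.fixture(scope="session")
def reference_tree_path():
    return data_path("reference_tree.nwk")


@pytest.fixture(scope="session")
def clades_path():
    return data_path("clades.tsv")


@pytest.fixture(scope="session")
def traits_path():
    return data_path("traits.tsv")
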