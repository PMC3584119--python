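"""Shared argument handling for the numbered analysis drivers.

Each driver operates on one pipeline run directory (default
``results/run_seed<seed>``) and can be re-run independently: stages read
their inputs back from disk, so the sequence 01..06 can be executed in
order, or any later stage re-run after tweaking nothing but its own
parameters.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from mitosig.pipeline import PipelineRun

RESULTS = Path(__file__).resolve().parents[1] / "results"


def make_run(description: str, extra=None) -> tuple[PipelineRun, argparse.Namespace]:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--run-dir", type=Path, default=None,
                        help="pipeline run directory "
                             "(default results/run_seed<seed>)")
    if extra is not None:
        extra(parser)
    args = parser.parse_args()
    run_dir = args.run_dir or RESULTS / f"run_seed{args.seed}"
    return PipelineRun(run_dir, seed=args.seed), args
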