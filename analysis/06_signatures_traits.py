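"""Driver 06: spacer presence-pattern classification, diagnostic tRNA-loop
motifs and parsimony trait mapping (writes signatures/ and traits/)."""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    run, _ = common.make_run(__doc__)
    patterns, motifs = run.signatures_stage()
    _, summary = run.traits_stage()
    print(f"{len(patterns)} spacer patterns, {len(motifs)} diagnostic "
          f"motifs under {run.dir}/signatures/")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
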