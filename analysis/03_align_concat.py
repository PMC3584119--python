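"""Driver 03: per-gene alignments (codon-aware for PCGs, structure-guided
for tRNAs) and named concatenations with partition files
(writes alignments/ and concat/)."""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    run, _ = common.make_run(__doc__)
    alns = run.align()
    concats = run.concat()
    print(f"aligned {len(alns)} genes, built {len(concats)} concatenations "
          f"under {run.dir}/")


if __name__ == "__main__":
    sys.exit(main())
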