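"""Driver 01: simulate a synthetic mitogenome bundle (writes truth/)."""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    run, _ = common.make_run(__doc__)
    truth = run.simulate()
    print(f"simulated {len(truth.taxa)} taxa under {run.dir}/truth/")


if __name__ == "__main__":
    sys.exit(main())
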