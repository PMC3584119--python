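"""Driver 04: p-distance matrices, bootstrapped within/among-clade summaries
and neighbour-joining trees for every concatenation (writes distances/)."""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    run, args = common.make_run(
        __doc__, extra=lambda p: p.add_argument("--n-boot", type=int,
                                                default=1000))
    out = run.distances(n_boot=args.n_boot)
    print(f"distance summaries for {sorted(out)} under {run.dir}/distances/")


if __name__ == "__main__":
    sys.exit(main())
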