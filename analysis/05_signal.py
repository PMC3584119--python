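"""Driver 05: quartet likelihood-mapping signal table for the standard
concatenation sets (writes signal/signal.tsv)."""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    run, args = common.make_run(
        __doc__, extra=lambda p: p.add_argument("--n-quartets", type=int,
                                                default=150))
    report = run.signal(n_quartets=args.n_quartets)
    print(report.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
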