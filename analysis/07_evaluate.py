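"""Driver 07: score the annotation against the simulation ground truth and
write the manifest (writes evaluation.json and manifest.json)."""

import importlib.util
import json
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    run, _ = common.make_run(__doc__)
    metrics = run.evaluate()
    run.write_manifest()
    print(json.dumps(metrics, indent=2, sort_keys=True))


if __name__ == "__main__":
    sys.exit(main())
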