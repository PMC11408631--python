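"""Rescale micromill profiles to the larval (0-60 dph) and juvenile
(106-120 dph) windows after the acid-fractionation correction.

Reads results/study/data/, writes stage_values.csv and validation.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from run_common import base_config, parse_args

from otoprov import pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = base_config(args) | {"stages": ["windows"]}
    manifest = pipeline.run_pipeline(cfg)
    st = manifest["stages"]["windows"]
    print(f"{st['n_fish']} fish with larval values; {st['n_violations']} validation flags")


if __name__ == "__main__":
    main()
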