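"""Classify fish into locals and nonlocals: per-year-class juvenile-d18O
thresholds, then the linear discriminant for age-1 fish lacking the juvenile
measurement, with leave-one-out cross-validation and proportion tables.

Writes thresholds.csv, classification.csv, loocv.json, proportions.csv.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from run_common import base_config, parse_args

from otoprov import pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = base_config(args) | {"stages": ["classify"]}
    pipeline.run_pipeline(cfg)
    with open(Path(args.out) / "loocv.json") as fh:
        loocv = json.load(fh)
    print(f"LOOCV: {loocv['n_correct']}/{loocv['n']} correct ({100*loocv['accuracy']:.1f}%)")
    for row in loocv["per_predicted"]:
        print(
            f"  predicted {row['predicted_label']}: {row['n_correct']}/{row['n_predicted']}"
            f" ({100*row['precision']:.0f}%) actually were"
        )


if __name__ == "__main__":
    main()
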