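"""Simulate the synthetic study: a two-year-class cohort of locals, nonlocals
and Pacific-offshore fish, plus the gridded temperature/salinity environment.

Writes results/study/data/{samples,segments,truth}.csv and environment.nc.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from run_common import base_config, parse_args

from otoprov import pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = base_config(args) | {"stages": ["simulate"]}
    manifest = pipeline.run_pipeline(cfg)
    print(f"simulated {manifest['stages']['simulate']['n_fish']} fish -> {args.out}/data/")


if __name__ == "__main__":
    main()
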