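"""Shared run configuration for the numbered analysis drivers.

All drivers operate on the same run directory (``results/study`` by default)
so each step picks up the previous step's files, mirroring the file-based
stage isolation of the pipeline.
"""

from __future__ import annotations

import argparse
import warnings


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="results/study")
    args = parser.parse_args()
    warnings.filterwarnings("ignore")
    return args


def base_config(args: argparse.Namespace) -> dict:
    return {"out_dir": args.out, "seed": args.seed}
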