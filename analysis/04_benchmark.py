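#!/usr/bin/env python
"""Benchmark predictions against the knockout-phenotype reference.

Maps the simulated knockout gene-phenotype pairs onto side-effect terms,
tests whether reference pairs have smaller q-values than the background
(one-sided KS with permutation p), and whether significant clusters match
reference pairs above the overall cluster match rate (one-sided Fisher).
Writes results/benchmark.tsv.
"""

import argparse
from pathlib import Path

import yaml

from sideminer import run_pipeline
from sideminer.benchmark import format_report, write_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    with open(args.out_dir / "config.yaml") as fh:
        config = yaml.safe_load(fh)
    config["out_dir"] = None
    result = run_pipeline(config)
    if result.benchmark is None:
        raise SystemExit("no knockout reference in the configured inputs")
    write_report(result.benchmark, args.out_dir / "benchmark.tsv")
    print(format_report(result.benchmark))


if __name__ == "__main__":
    main()
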