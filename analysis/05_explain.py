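#!/usr/bin/env python
"""Attribute observed drug-side-effect pairs to main and off-targets.

For every observed drug-side-effect pair whose side effect has a
predicted causal protein, looks for significant targets among the drug's
own targets and classifies the pair as explained by the main target
only, by off-targets only, by both, or unexplained; also breaks the
explained fraction down by protein family.  Writes
results/explanation_summary.tsv.
"""

import argparse
from pathlib import Path

import yaml

from sideminer import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    with open(args.out_dir / "config.yaml") as fh:
        config = yaml.safe_load(fh)
    config["out_dir"] = None
    result = run_pipeline(config)
    df = result.explanation
    df.to_csv(args.out_dir / "explanation_summary.tsv", sep="\t", index=False)

    cat = df[df.block == "category"].set_index("key")
    print(f"{df.attrs['n_pairs']} observed drug-side-effect pairs considered "
          f"({int(cat.denominator.iloc[0])} for drugs with known main targets):")
    for key, row in cat.iterrows():
        print(f"  {key:>11}: {row.fraction:6.1%}  ({int(row['count'])} pairs)")
    fam = df[df.block == "family"].set_index("key")
    print("explained by family:")
    for key, row in fam.iterrows():
        if row["count"]:
            print(f"  {key:>16}: {row.fraction:6.1%}")


if __name__ == "__main__":
    main()
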