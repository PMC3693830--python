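#!/usr/bin/env python
"""Predict causal protein-side-effect pairs on the simulated world.

Runs preprocessing (virtual mode targets, Hobohm de-redundancy, target
merging, minimum support) and the Fisher/q-value enrichment, and writes
results/predictions.tsv.  Also reproduces the textbook worked example:
12 drugs inhibit a beta-adrenergic-receptor-like target, 11 of them cause
bradycardia, 184 of 550 drugs cause it overall, giving p ~ 4e-5.
"""

import argparse
from pathlib import Path

import yaml

from sideminer import (
    build_virtual_targets,
    filter_min_support,
    fisher_greater,
    merge_equivalent_targets,
    run_enrichment,
    run_pipeline,
    select_significant,
    worked_example_fixture,
    write_predictions,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    with open(args.out_dir / "config.yaml") as fh:
        config = yaml.safe_load(fh)
    config["out_dir"] = None  # artifacts written below
    result = run_pipeline(config)
    write_predictions(result.predictions, args.out_dir / "predictions.tsv")

    sig = select_significant(result.predictions, config.get("q_cutoff", 0.01))
    print(f"{len(result.predictions)} pairs tested, {len(sig)} significant "
          f"at q < {config.get('q_cutoff', 0.01)}")
    print("strongest predictions:")
    for r in result.predictions[:5]:
        print(f"  {r.target.key} -> {r.se_id}: a={r.table.a}/"
              f"{r.table.n_binders} binders, p={r.p:.3g}, q={r.q:.3g}")

    net = build_virtual_targets(worked_example_fixture())
    net, _ = merge_equivalent_targets(net)
    net = filter_min_support(net, 5)
    (hit,) = [r for r in run_enrichment(net)
              if "ADRB1" in r.target.base_proteins and r.se_id == "C0428977"]
    t = hit.table
    print(f"worked example: table ({t.a},{t.b},{t.c},{t.d}) of {t.n} drugs "
          f"-> one-sided Fisher p = {hit.p:.2e}")


if __name__ == "__main__":
    main()
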