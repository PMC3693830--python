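#!/usr/bin/env python
"""Cluster the significant predictions and score recovery of the truth.

Co-bound targets predicted for the same side effect are grouped into
clusters (connected components of the >= 50% co-binding graph); the
planted causal relations of the simulated world are then scored at
cluster level.  Writes results/clusters.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd
import yaml

from sideminer import recovery_report, run_pipeline
from sideminer.clustering import write_clusters


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    with open(args.out_dir / "config.yaml") as fh:
        config = yaml.safe_load(fh)
    config["out_dir"] = None
    result = run_pipeline(config)
    write_clusters(result.clusters, args.out_dir / "clusters.tsv")

    sizes = pd.Series([len(c.members) for c in result.clusters])
    seeded = sum(c.seed is not None for c in result.clusters)
    print(f"{len(result.clusters)} clusters over "
          f"{len({c.se_id for c in result.clusters})} side effects; "
          f"median size {sizes.median():.0f}, max {sizes.max()}; "
          f"{seeded} seeded by a known causal protein")

    truth = pd.read_csv(Path(config["inputs"]["drug_target"]).parent / "truth.tsv",
                        sep="\t")
    truth_set = set(truth.itertuples(index=False, name=None))
    rep = recovery_report(result.predictions, result.clusters, truth_set)
    print(f"recovery vs planted truth: recall {rep.recall:.2f} "
          f"({rep.n_recovered}/{rep.n_truth}), cluster FDR "
          f"{rep.empirical_fdr if rep.empirical_fdr is not None else 'n/a'}")


if __name__ == "__main__":
    main()
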