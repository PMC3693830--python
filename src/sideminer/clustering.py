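"""Co-binding clusters of predicted causal targets.

Most drugs bind several members of the same protein family or complex, so
a side effect caused by one protein drags pharmacologically
indistinguishable neighbours into significance.  Predicted targets of one
side effect are therefore grouped into clusters: two targets are linked
when at least half of the drugs binding one also bind the other, and
clusters are the connected components of that graph.  A verified member
then accounts for the whole cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import pandas as pd

from .data_io import StudyNetwork


@dataclass
class TargetCluster:
    """A per-side-effect group of predicted causal target nodes."""

    se_id: str
    cluster_id: str
    members: list  # TargetNode, ordered by q
    seed: Optional[str] = None  # known causal base protein contained, if any
    representative_q: float = float("nan")

    @property
    def base_proteins(self) -> set:
        return set().union(*(t.base_proteins for t in self.members))


def cobinding_fraction(t1: str, t2: str, network: StudyNetwork) -> float:
    """Fraction of active drugs binding t1 that also bind t2 (directional)."""
    d1 = network.target_drugs.get(t1, set()) & network.active_drug_set
    d2 = network.target_drugs.get(t2, set()) & network.active_drug_set
    if not d1:
        raise ValueError(f"target {t1} has no active drugs")
    return len(d1 & d2) / len(d1)


def build_side_effect_clusters(
    se_id: str,
    significant_records,
    network: StudyNetwork,
    known_causal: set = frozenset(),
    threshold: float = 0.5,
):
    """Cluster the significant targets of one side effect.

    An undirected link is created between two targets when the co-binding
    fraction reaches ``threshold`` in either direction; clusters are the
    connected components (single linkage), so every significant target
    lands in exactly one cluster.  When a cluster contains proteins known
    to cause the side effect, the one whose record has the smallest q
    becomes the cluster seed; further known proteins remain plain members.
    """
    records = sorted(significant_records, key=lambda r: (r.q, r.p, r.target.key))
    keys = [r.target.key for r in records]
    by_key = {r.target.key: r for r in records}

    graph = nx.Graph()
    graph.add_nodes_from(keys)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1:]:
            if (
                cobinding_fraction(k1, k2, network) >= threshold
                or cobinding_fraction(k2, k1, network) >= threshold
            ):
                graph.add_edge(k1, k2)

    causal_proteins = {p for p, s in known_causal if s == se_id}
    clusters = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(by_key[k].q for k in c))
    for idx, component in enumerate(components):
        members = sorted(component, key=lambda k: (by_key[k].q, k))
        seed = None
        seeds = [
            (by_key[k].q, p)
            for k in members
            for p in sorted(network.targets[k].base_proteins & causal_proteins)
        ]
        if seeds:
            seed = min(seeds)[1]
        clusters.append(
            TargetCluster(
                se_id=se_id,
                cluster_id=f"{se_id}/c{idx}",
                members=[network.targets[k] for k in members],
                seed=seed,
                representative_q=by_key[members[0]].q,
            )
        )
    return clusters


def cluster_predictions(
    records,
    network: StudyNetwork,
    known_causal: set = frozenset(),
    q_cutoff: float = 0.01,
    threshold: float = 0.5,
):
    """Cluster all significant predictions and stamp cluster ids on records."""
    from .enrichment import select_significant

    significant = select_significant(records, q_cutoff)
    by_se: dict = {}
    for r in significant:
        by_se.setdefault(r.se_id, []).append(r)

    clusters = []
    assignment = {}
    for se_id in sorted(by_se):
        for cluster in build_side_effect_clusters(
            se_id, by_se[se_id], network, known_causal, threshold
        ):
            clusters.append(cluster)
            for node in cluster.members:
                assignment[(node.key, se_id)] = cluster.cluster_id
    for r in records:
        r.cluster_id = assignment.get((r.target.key, r.se_id))
    return clusters


def count_clusters(predictions, network, q_cutoff: float = 0.01, threshold: float = 0.5):
    """Number of co-binding clusters per side effect and in total.

    The cluster — not the individual protein — is the counting unit for
    benchmarking, so that families of co-bound proteins are not counted
    as independent predictions.
    """
    clusters = cluster_predictions(
        predictions, network, q_cutoff=q_cutoff, threshold=threshold
    )
    per_se: dict = {}
    for c in clusters:
        per_se[c.se_id] = per_se.get(c.se_id, 0) + 1
    return per_se, len(clusters)


def write_clusters(clusters, path) -> None:
    rows = [
        {
            "se_id": c.se_id,
            "cluster_id": c.cluster_id,
            "members": ";".join(t.key for t in c.members),
            "seed": c.seed or "",
            "representative_q": repr(c.representative_q),
        }
        for c in clusters
    ]
    pd.DataFrame(
        rows, columns=["se_id", "cluster_id", "members", "seed", "representative_q"]
    ).to_csv(path, sep="\t", index=False)
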