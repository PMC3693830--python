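"""Network construction steps that precede enrichment testing.

Covers the four preprocessing stages: action-mode virtual targets, chemical
de-redundancy of drugs (Tanimoto similarity + Hobohm reduction), merging of
targets that are indistinguishable from drug-target data, and the
minimum-support filter, plus the post-hoc metabolizing-enzyme flag.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

from .data_io import Fingerprint, StudyNetwork, TargetNode

logger = logging.getLogger("sideminer")


def build_virtual_targets(
    network: StudyNetwork, mode_annotations: Optional[Mapping] = None
) -> StudyNetwork:
    """Add mode-specific virtual target nodes next to each generic node.

    Every drug-protein edge keeps its generic ``(protein, binding)`` node;
    where the drug is annotated to activate or inhibit the protein, an
    additional edge to the virtual ``(protein, activation)`` or
    ``(protein, inhibition)`` node is created.  A beta blocker, for
    example, gains virtual inhibited beta-adrenergic-receptor targets that
    are tested independently of the generic binding nodes.

    Mode annotations for drug-protein pairs that are not edges of the
    network are ignored with a warning.
    """
    if mode_annotations is None:
        mode_annotations = network.mode_annotations
    net = network.copy()
    for (drug_id, protein_id), modes in mode_annotations.items():
        generic = f"{protein_id}:binding"
        if generic not in net.target_drugs or drug_id not in net.target_drugs[generic]:
            logger.warning(
                "mode annotation for absent edge (%s, %s) ignored", drug_id, protein_id
            )
            continue
        for mode in modes:
            node = TargetNode(protein_id, mode)
            net.targets.setdefault(node.key, node)
            net.target_drugs.setdefault(node.key, set()).add(drug_id)
    return net


def merge_equivalent_targets(network: StudyNetwork):
    """Collapse target nodes bound by the same set of active drugs.

    Targets associated with identical drug sets cannot be distinguished by
    the association statistics, so they are represented by one node whose
    ``merged_members`` lists all originals.  Drug sets are compared over
    ``active_drug_set``; the merged node's edges are the union of the
    members' edges (identical over the active set by construction).

    Returns the merged network and a map ``merged_key -> {member_key ->
    original drug set}`` from which the original edge multiset can be
    reconstructed exactly.
    """
    net = network.copy()
    groups: dict = {}
    for key in sorted(net.targets):
        signature = frozenset(net.target_drugs.get(key, set()) & net.active_drug_set)
        groups.setdefault(signature, []).append(key)

    merged_targets: dict = {}
    merged_edges: dict = {}
    merge_map: dict = {}
    for keys in groups.values():
        members = frozenset(
            member
            for key in keys
            for member in net.targets[key].merged_members
        )
        rep = net.targets[keys[0]]  # lexicographically smallest key
        node = TargetNode(rep.protein_id, rep.mode, members)
        if node.key in merged_targets:  # same representative from two groups
            raise AssertionError(f"representative collision on {node.key}")
        merged_targets[node.key] = node
        merged_edges[node.key] = set().union(
            *(net.target_drugs.get(key, set()) for key in keys)
        )
        merge_map[node.key] = {
            key: frozenset(net.target_drugs.get(key, set())) for key in keys
        }
    n_before, n_after = len(net.targets), len(merged_targets)
    if n_after < n_before:
        logger.info("merged %d target nodes into %d", n_before, n_after)
    net.targets = merged_targets
    net.target_drugs = merged_edges
    return net, merge_map


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two equal-length fingerprints.

    Two all-zero fingerprints have similarity 0 by convention.
    """
    if fp_a.length != fp_b.length:
        raise ValueError(
            f"fingerprint length mismatch: {fp_a.length} vs {fp_b.length}"
        )
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        return 0.0
    return len(fp_a.bits & fp_b.bits) / union


def similarity_graph(drugs: Iterable[str], fingerprints: Mapping, cutoff: float) -> dict:
    """Adjacency over drugs with pairwise Tanimoto similarity > cutoff."""
    ids = sorted(d for d in drugs if d in fingerprints)
    adj: dict = {d: set() for d in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if tanimoto(fingerprints[a], fingerprints[b]) > cutoff:
                adj[a].add(b)
                adj[b].add(a)
    return adj


def hobohm_reduce(drugs: set, fingerprints: Mapping, cutoff: float = 0.7) -> set:
    """Greedy redundancy removal over chemical similarity (Hobohm, alg. 2).

    Repeatedly removes the drug with the most neighbours above the
    similarity cutoff until no similar pair remains.  Ties are broken by
    removing the lexicographically greatest drug id, making the reduction
    deterministic.  Drugs without a fingerprint cannot be compared and are
    kept unconditionally (with a warning).
    """
    missing = sorted(d for d in drugs if d not in fingerprints)
    if missing:
        logger.warning(
            "%d drugs lack fingerprints and are kept unconditionally", len(missing)
        )
    adj = similarity_graph(drugs, fingerprints, cutoff)
    removed = set()
    while True:
        degrees = {d: len(nbrs) for d, nbrs in adj.items() if nbrs}
        if not degrees:
            break
        max_deg = max(degrees.values())
        victim = max(d for d, deg in degrees.items() if deg == max_deg)
        removed.add(victim)
        for nbr in adj.pop(victim):
            adj[nbr].discard(victim)
    kept = set(drugs) - removed
    # post-condition asserted on every run: no kept pair is similar
    for a in adj:
        assert not adj[a], f"kept pair above cutoff involving {a}"
    return kept


def filter_min_support(network: StudyNetwork, min_drugs: int = 5) -> StudyNetwork:
    """Drop targets and side effects associated with too few active drugs.

    Entities supported by fewer than ``min_drugs`` drugs of the active set
    carry too little signal for confident testing and are removed.  Drugs
    themselves are never removed, so a single pass suffices (removals
    cannot cascade).
    """
    net = network.copy()
    keep_targets = {
        key for key in net.targets
        if len(net.target_drugs.get(key, set()) & net.active_drug_set) >= min_drugs
    }
    keep_ses = {
        term for term in net.side_effects
        if len(net.se_drugs.get(term, set()) & net.active_drug_set) >= min_drugs
    }
    logger.info(
        "min-support %d: %d/%d targets, %d/%d side effects kept",
        min_drugs, len(keep_targets), len(net.targets),
        len(keep_ses), len(net.side_effects),
    )
    net.targets = {k: v for k, v in net.targets.items() if k in keep_targets}
    net.target_drugs = {k: v for k, v in net.target_drugs.items() if k in keep_targets}
    net.side_effects = {k: v for k, v in net.side_effects.items() if k in keep_ses}
    net.se_drugs = {k: v for k, v in net.se_drugs.items() if k in keep_ses}
    return net


def flag_metabolizing_exclusions(predictions, metabolizing: set):
    """Flag predictions for metabolizing enzymes (in place; returns records).

    Metabolizing enzymes can elicit side effects only indirectly (through
    shared active metabolites or altered exposure to other chemicals), so
    their predictions are excluded from significance counts, clustering
    and explanation.  A merged node is flagged if ANY member protein is
    metabolizing.  Flagged records stay in the output table.
    """
    for record in predictions:
        record.excluded = bool(record.target.base_proteins & metabolizing)
    return predictions
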