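"""Synthetic study worlds with known ground truth.

No accession-ready snapshot of the drug/side-effect/target universe is
redistributable, so pipeline behaviour is established on generated worlds
that mimic its statistical structure: drugs bind family-structured target
panels, a set of planted causal (protein, mode, side effect) relations
elicits side effects with a given penetrance on top of background label
noise (noisy-OR), fingerprints carry family resemblance plus deliberate
near-duplicate drugs, and a knockout-phenotype reference covers the
planted truth with partial sensitivity plus decoys.

Also provides the small worked-example network with the printed
beta-blocker/bradycardia counts, and recovery scoring of pipeline output
against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import (
    AnnotationBundle,
    DrugRecord,
    Fingerprint,
    SideEffectTerm,
    StudyNetwork,
    TargetNode,
)
from .explain import FAMILIES


@dataclass
class GeneratorParams:
    """Knobs of the synthetic world; defaults are the study conditions.

    A drug picks one primary protein family and binds each member with
    probability ``beta`` and every outside protein with probability
    ``epsilon``.  A drug elicits side effect s with probability
    1 - (1 - background_rate) * prod(1 - penetrance) over the planted
    causal targets the drug perturbs with matching annotated mode.
    """

    n_proteins: int = 100
    n_families: int = 20
    family_sizes: Optional[tuple] = None  # default: near-equal split
    n_drugs: int = 300
    beta: float = 0.8  # in-family binding probability
    epsilon: float = 0.02  # off-family binding probability
    n_side_effects: int = 50
    n_planted: int = 30
    penetrance: float = 0.8
    background_rate: float = 0.05
    mode_known_prob: float = 0.7  # edge carries an action-mode annotation
    mode_fidelity: float = 0.9  # annotated mode equals the protein's dominant mode
    fingerprint_length: int = 128
    mutation_rate: float = 0.3  # per-bit flips from the family prototype
    n_near_clones: int = 10
    clone_mutation_rate: float = 0.02
    ko_sensitivity: float = 0.8
    n_ko_decoys: int = 20
    n_unmapped_phenotypes: int = 2
    n_metabolizing: int = 5
    known_causal_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "beta", "epsilon", "penetrance", "background_rate",
            "mode_known_prob", "mode_fidelity", "mutation_rate",
            "clone_mutation_rate", "ko_sensitivity", "known_causal_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_proteins", "n_families", "n_drugs", "n_side_effects",
                     "fingerprint_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_families > self.n_proteins:
            raise ValueError("more families than proteins")
        if self.family_sizes is not None and sum(self.family_sizes) != self.n_proteins:
            raise ValueError("family_sizes must sum to n_proteins")
        if self.n_planted > min(self.n_proteins - self.n_metabolizing,
                                self.n_side_effects):
            raise ValueError("too many planted pairs for the entity counts")


@dataclass
class SyntheticWorld:
    network: StudyNetwork
    fingerprints: dict  # drug_id -> Fingerprint
    annotations: AnnotationBundle
    truth: set  # {(protein_id, mode, se_id)}
    params: GeneratorParams = field(repr=False, default=None)


def _family_sizes(params: GeneratorParams) -> list:
    if params.family_sizes is not None:
        return list(params.family_sizes)
    base, extra = divmod(params.n_proteins, params.n_families)
    return [base + (1 if i < extra else 0) for i in range(params.n_families)]


def simulate_world(params: GeneratorParams) -> SyntheticWorld:
    """Generate one world; fully deterministic given ``params`` (incl. seed)."""
    rng = np.random.default_rng(params.seed)

    proteins = [f"P{i:04d}" for i in range(params.n_proteins)]
    sizes = _family_sizes(params)
    family_of_protein: dict = {}
    members: list = []
    start = 0
    for fam_idx, size in enumerate(sizes):
        fam = f"FAM{fam_idx:02d}"
        block = proteins[start:start + size]
        members.append(block)
        for p in block:
            family_of_protein[p] = fam_idx
        start += size

    dominant_mode = {
        p: ("activation" if rng.random() < 0.5 else "inhibition") for p in proteins
    }

    n_regular = params.n_drugs
    regular = [f"D{i:04d}" for i in range(n_regular)]
    n_clones = min(params.n_near_clones, n_regular)
    clones = [f"{d}x" for d in regular[:n_clones]]
    drugs = regular + clones

    metabolizing = set(
        rng.choice(proteins, size=params.n_metabolizing, replace=False)
    ) if params.n_metabolizing else set()

    eligible = sorted(set(proteins) - metabolizing)
    planted_proteins = rng.choice(eligible, size=params.n_planted, replace=False)
    ses = [f"SE{i:04d}" for i in range(params.n_side_effects)]
    planted_ses = rng.choice(ses, size=params.n_planted, replace=False)
    truth = {
        (p, dominant_mode[p], s) for p, s in zip(planted_proteins, planted_ses)
    }
    causal_by_se: dict = {}
    for p, mode, s in truth:
        causal_by_se.setdefault(s, []).append((p, mode))

    net = StudyNetwork()
    for d in drugs:
        net.drugs[d] = DrugRecord(d, fingerprint_ref=d)
    for s in ses:
        net.side_effects[s] = SideEffectTerm(s)
        net.se_drugs[s] = set()

    # binding profiles and mode annotations
    primary_family = {d: int(rng.integers(params.n_families)) for d in regular}
    binds: dict = {}
    edge_mode: dict = {}
    for d in regular:
        fam = primary_family[d]
        bound = set()
        for p in members[fam]:
            if rng.random() < params.beta:
                bound.add(p)
        for fam_idx, block in enumerate(members):
            if fam_idx == fam:
                continue
            for p in block:
                if rng.random() < params.epsilon:
                    bound.add(p)
        binds[d] = bound
        for p in sorted(bound):
            if rng.random() < params.mode_known_prob:
                dom = dominant_mode[p]
                other = "inhibition" if dom == "activation" else "activation"
                edge_mode[(d, p)] = dom if rng.random() < params.mode_fidelity else other
    # clones copy the binding profile (and mode annotations) of their base
    for base, clone in zip(regular[:n_clones], clones):
        primary_family[clone] = primary_family[base]
        binds[clone] = set(binds[base])
        for p in binds[base]:
            if (base, p) in edge_mode:
                edge_mode[(clone, p)] = edge_mode[(base, p)]

    for d in drugs:
        for p in binds[d]:
            node = TargetNode(p, "binding")
            net.targets.setdefault(node.key, node)
            net.target_drugs.setdefault(node.key, set()).add(d)
            if (d, p) in edge_mode:
                net.mode_annotations.setdefault((d, p), set()).add(edge_mode[(d, p)])

    # side effects via noisy-OR of background and matching-mode causal hits
    for d in drugs:
        for s in ses:
            p_not = 1.0 - params.background_rate
            for protein, mode in causal_by_se.get(s, ()):
                if edge_mode.get((d, protein)) == mode:
                    p_not *= 1.0 - params.penetrance
            if rng.random() < 1.0 - p_not:
                net.se_drugs[s].add(d)

    net.active_drug_set = set(drugs)
    net.validate()

    # fingerprints: family prototype + per-bit mutation; clones are
    # low-mutation copies of their base drug
    L = params.fingerprint_length
    prototypes = rng.random((params.n_families, L)) < 0.5
    fp_bits: dict = {}
    for d in regular:
        proto = prototypes[primary_family[d]]
        flips = rng.random(L) < params.mutation_rate
        fp_bits[d] = proto ^ flips
    for base, clone in zip(regular[:n_clones], clones):
        flips = rng.random(L) < params.clone_mutation_rate
        fp_bits[clone] = fp_bits[base] ^ flips
    fingerprints = {
        d: Fingerprint(d, frozenset(np.flatnonzero(bits).tolist()), L)
        for d, bits in fp_bits.items()
    }

    # annotations
    annotations = AnnotationBundle(metabolizing=metabolizing)
    fam_class = [FAMILIES[i % (len(FAMILIES) - 1)] for i in range(params.n_families)]
    for p in proteins:
        annotations.family_counts[p] = {fam_class[family_of_protein[p]]: 3}
    for d in regular + clones:
        fam = primary_family[d]
        in_family = sorted(binds[d] & set(members[fam]))
        if in_family:
            annotations.main_targets[d] = {in_family[0]}
    for p, mode, s in sorted(truth):
        if rng.random() < params.known_causal_fraction:
            annotations.known_causal.add((p, s))

    # knockout reference: planted pairs at partial sensitivity, plus decoys
    phenotype_of = {s: f"MP:{s}" for s in ses}
    annotations.phenotype_synonyms = {ph: s for s, ph in phenotype_of.items()}
    for p, mode, s in sorted(truth):
        if rng.random() < params.ko_sensitivity:
            annotations.ko_reference.add((p, phenotype_of[s]))
    planted_pairs = {(p, s) for p, _, s in truth}
    n_decoys = 0
    while n_decoys < params.n_ko_decoys:
        p = proteins[int(rng.integers(params.n_proteins))]
        s = ses[int(rng.integers(params.n_side_effects))]
        if (p, s) in planted_pairs:
            continue
        pair = (p, phenotype_of[s])
        if pair in annotations.ko_reference:
            continue
        annotations.ko_reference.add(pair)
        n_decoys += 1
    for i in range(params.n_unmapped_phenotypes):
        p = proteins[int(rng.integers(params.n_proteins))]
        annotations.ko_reference.add((p, f"MP:unmapped{i}"))

    return SyntheticWorld(
        network=net, fingerprints=fingerprints,
        annotations=annotations, truth=truth, params=params,
    )


def worked_example_fixture() -> StudyNetwork:
    """The printed worked-example network, padded so filters pass.

    550 drugs; a beta-adrenergic-receptor-like target inhibited by 12
    drugs, 11 of which are labelled with bradycardia; 184 drugs in total
    carry the bradycardia label.  Two inert padding entities keep the
    minimum-support filter non-trivial.
    """
    net = StudyNetwork()
    drugs = [f"D{i:03d}" for i in range(1, 551)]
    for d in drugs:
        net.drugs[d] = DrugRecord(d)

    binders = drugs[:12]  # D001..D012
    brady = "C0428977"  # bradycardia concept id
    net.side_effects[brady] = SideEffectTerm(brady, "bradycardia")
    # 11 of the 12 binders plus 173 non-binders elicit bradycardia
    net.se_drugs[brady] = set(drugs[:11]) | set(drugs[12:185])

    node = TargetNode("ADRB1", "binding")
    net.targets[node.key] = node
    net.target_drugs[node.key] = set(binders)
    for d in binders:
        net.mode_annotations[(d, "ADRB1")] = {"inhibition"}

    pad_target = TargetNode("PAD1", "binding")
    net.targets[pad_target.key] = pad_target
    net.target_drugs[pad_target.key] = set(drugs[179:200])
    pad_se = "C_PAD"
    net.side_effects[pad_se] = SideEffectTerm(pad_se)
    net.se_drugs[pad_se] = set(drugs[199:260])
    # every drug carries at least one label, as in real package-insert data
    pad_se2 = "C_PAD2"
    net.side_effects[pad_se2] = SideEffectTerm(pad_se2)
    net.se_drugs[pad_se2] = set(drugs[260:])

    net.active_drug_set = set(drugs)
    net.validate()
    return net


@dataclass
class RecoveryReport:
    recall: Optional[float]  # None when the truth is empty
    precision: Optional[float]  # None when there are no significant clusters
    empirical_fdr: Optional[float]
    n_recovered: int
    n_truth: int
    n_clusters: int
    n_matched_clusters: int


def recovery_report(predictions, clusters, truth: set, q_cutoff: float = 0.01) -> RecoveryReport:
    """Score pipeline output against the planted truth at cluster level.

    A planted (protein, mode, side effect) relation is recovered when
    some significant cluster for its side effect contains the protein.
    The empirical FDR is the fraction of significant clusters containing
    no planted protein for their side effect.
    """
    planted_by_se: dict = {}
    for p, mode, s in truth:
        planted_by_se.setdefault(s, set()).add(p)

    recovered = 0
    for p, mode, s in truth:
        if any(c.se_id == s and p in c.base_proteins for c in clusters):
            recovered += 1

    matched = sum(
        bool(c.base_proteins & planted_by_se.get(c.se_id, set())) for c in clusters
    )
    n_clusters = len(clusters)
    return RecoveryReport(
        recall=recovered / len(truth) if truth else None,
        precision=matched / n_clusters if n_clusters else None,
        empirical_fdr=(n_clusters - matched) / n_clusters if n_clusters else None,
        n_recovered=recovered,
        n_truth=len(truth),
        n_clusters=n_clusters,
        n_matched_clusters=matched,
    )


# ---------------------------------------------------------------------------
# flat-file export, so `simulate` feeds the same readers as real data


def write_world(world: SyntheticWorld, out_dir) -> dict:
    """Write a world as the TSV table set consumed by the pipeline.

    Returns the path map usable as the pipeline config ``inputs`` entry.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = world.network

    rows = []
    for key in sorted(net.target_drugs):
        node = net.targets[key]
        for d in sorted(net.target_drugs[key]):
            modes = net.mode_annotations.get((d, node.protein_id), ())
            if modes:
                for mode in sorted(modes):
                    rows.append((d, node.protein_id, 0.9, mode))
            else:
                rows.append((d, node.protein_id, 0.9, ""))
    pd.DataFrame(rows, columns=["drug_id", "protein_id", "confidence", "mode"]).to_csv(
        out / "drug_target.tsv", sep="\t", index=False
    )

    rows = [
        (d, s)
        for s in sorted(net.se_drugs)
        for d in sorted(net.se_drugs[s])
    ]
    pd.DataFrame(rows, columns=["drug_id", "se_id"]).to_csv(
        out / "drug_se.tsv", sep="\t", index=False
    )

    rows = []
    for d in sorted(world.fingerprints):
        fp = world.fingerprints[d]
        bits = "".join("1" if i in fp.bits else "0" for i in range(fp.length))
        rows.append((d, bits))
    pd.DataFrame(rows, columns=["drug_id", "fingerprint"]).to_csv(
        out / "fingerprints.tsv", sep="\t", index=False
    )

    ann = world.annotations
    pd.DataFrame(
        [(d, p) for d in sorted(ann.main_targets) for p in sorted(ann.main_targets[d])],
        columns=["drug_id", "protein_id"],
    ).to_csv(out / "main_targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (p, fam, n)
            for p in sorted(ann.family_counts)
            for fam, n in sorted(ann.family_counts[p].items())
        ],
        columns=["protein_id", "family", "count"],
    ).to_csv(out / "family_counts.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(ann.metabolizing), columns=["protein_id"]).to_csv(
        out / "metabolizing.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(ann.known_causal), columns=["protein_id", "se_id"]).to_csv(
        out / "known_causal.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(ann.ko_reference), columns=["protein_id", "phenotype"]).to_csv(
        out / "ko_reference.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(ann.phenotype_synonyms.items()), columns=["phenotype", "se_id"]
    ).to_csv(out / "phenotype_synonyms.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(world.truth), columns=["protein_id", "mode", "se_id"]).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )

    return {
        "drug_target": str(out / "drug_target.tsv"),
        "drug_se": str(out / "drug_se.tsv"),
        "fingerprints": str(out / "fingerprints.tsv"),
        "annotations": {
            "main_targets": str(out / "main_targets.tsv"),
            "family_counts": str(out / "family_counts.tsv"),
            "metabolizing": str(out / "metabolizing.tsv"),
            "known_causal": str(out / "known_causal.tsv"),
            "ko_reference": str(out / "ko_reference.tsv"),
            "phenotype_synonyms": str(out / "phenotype_synonyms.tsv"),
        },
    }
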