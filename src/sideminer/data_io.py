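"""Domain types, flat-file readers/writers and pipeline orchestration.

All tables are tab-separated text with a header line; lines starting with
``#`` are comments.  The drug-target and drug-side-effect tables mirror the
flat-file layout of public drug annotation resources (one edge per row, with
an optional confidence score and an optional action-mode column on the
target side), so real exports can be dropped in without conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger("sideminer")

#: Recognised action modes for a target node.  ``binding`` is the generic
#: node every drug-protein edge contributes to; ``activation``/``inhibition``
#: are the virtual mode-specific nodes.
MODES = ("binding", "activation", "inhibition")

#: Synonyms accepted in input files for the two specific action modes.
MODE_ALIASES = {
    "activation": "activation",
    "agonist": "activation",
    "activator": "activation",
    "inhibition": "inhibition",
    "antagonist": "inhibition",
    "inhibitor": "inhibition",
}


@dataclass(frozen=True)
class DrugRecord:
    """A marketed drug, identified by an opaque id."""

    drug_id: str
    name: Optional[str] = None
    fingerprint_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")


@dataclass(frozen=True)
class TargetNode:
    """A protein target node, possibly mode-specific and possibly merged.

    ``merged_members`` lists the ``(protein_id, mode)`` pairs this node
    stands for; a plain node contains only itself.  Proteins bound by the
    same set of drugs are indistinguishable from drug-target data and are
    collapsed into one node.
    """

    protein_id: str
    mode: str
    merged_members: frozenset = None  # frozenset[(protein_id, mode)]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.merged_members is None:
            object.__setattr__(
                self, "merged_members", frozenset({(self.protein_id, self.mode)})
            )
        if (self.protein_id, self.mode) not in self.merged_members:
            raise ValueError("merged_members must include the node itself")

    @property
    def key(self) -> str:
        return f"{self.protein_id}:{self.mode}"

    @property
    def base_proteins(self) -> frozenset:
        """Base protein ids represented by this node (mode-agnostic)."""
        return frozenset(p for p, _ in self.merged_members)


@dataclass(frozen=True)
class SideEffectTerm:
    """A side-effect term from a controlled vocabulary (UMLS-style id)."""

    term_id: str
    label: Optional[str] = None


@dataclass
class StudyNetwork:
    """Drugs, target nodes and side effects with their two bipartite edge sets.

    ``active_drug_set`` is the non-redundant drug subset used for
    enrichment counting; edges of removed drugs are retained for the
    per-drug explanation stage.
    """

    drugs: dict = field(default_factory=dict)  # drug_id -> DrugRecord
    targets: dict = field(default_factory=dict)  # node key -> TargetNode
    side_effects: dict = field(default_factory=dict)  # term_id -> SideEffectTerm
    target_drugs: dict = field(default_factory=dict)  # node key -> set[drug_id]
    se_drugs: dict = field(default_factory=dict)  # term_id -> set[drug_id]
    active_drug_set: set = field(default_factory=set)
    # (drug_id, protein_id) -> set of specific modes, kept for virtual-target
    # construction.
    mode_annotations: dict = field(default_factory=dict)

    def validate(self) -> None:
        for key, drugs in self.target_drugs.items():
            if key not in self.targets:
                raise ValueError(f"edge references unknown target {key}")
            unknown = drugs - self.drugs.keys()
            if unknown:
                raise ValueError(f"target {key} references unknown drugs {unknown}")
        for term, drugs in self.se_drugs.items():
            if term not in self.side_effects:
                raise ValueError(f"edge references unknown side effect {term}")
            unknown = drugs - self.drugs.keys()
            if unknown:
                raise ValueError(f"side effect {term} references unknown drugs {unknown}")
        if not self.active_drug_set <= self.drugs.keys():
            raise ValueError("active_drug_set must be a subset of drugs")

    @property
    def drug_target_edges(self) -> set:
        return {(d, key) for key, drugs in self.target_drugs.items() for d in drugs}

    @property
    def drug_se_edges(self) -> set:
        return {(d, term) for term, drugs in self.se_drugs.items() for d in drugs}

    def active_binders(self, target_key: str) -> set:
        return self.target_drugs[target_key] & self.active_drug_set

    def active_elicitors(self, term_id: str) -> set:
        return self.se_drugs[term_id] & self.active_drug_set

    def copy(self) -> "StudyNetwork":
        return StudyNetwork(
            drugs=dict(self.drugs),
            targets=dict(self.targets),
            side_effects=dict(self.side_effects),
            target_drugs={k: set(v) for k, v in self.target_drugs.items()},
            se_drugs={k: set(v) for k, v in self.se_drugs.items()},
            active_drug_set=set(self.active_drug_set),
            mode_annotations={k: set(v) for k, v in self.mode_annotations.items()},
        )


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length 2D chemical fingerprint as a bit set."""

    drug_id: str
    bits: frozenset  # indices of set bits
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("fingerprint length must be positive")
        if self.bits and max(self.bits) >= self.length:
            raise ValueError("bit index exceeds fingerprint length")


@dataclass
class AnnotationBundle:
    """Optional annotation tables consumed by later pipeline stages."""

    main_targets: dict = field(default_factory=dict)  # drug_id -> set[protein_id]
    family_counts: dict = field(default_factory=dict)  # protein_id -> {family: count}
    metabolizing: set = field(default_factory=set)  # protein_id
    known_causal: set = field(default_factory=set)  # (protein_id, term_id)
    ko_reference: set = field(default_factory=set)  # (protein_id, phenotype)
    phenotype_synonyms: dict = field(default_factory=dict)  # phenotype -> term_id


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_network_tables(
    drug_target_path, drug_se_path, confidence_cutoff: float = 0.5
) -> StudyNetwork:
    """Read the drug-target and drug-side-effect edge tables.

    Target edges with a confidence score below ``confidence_cutoff`` are
    dropped (mirroring the confidence filter applied to interaction-database
    exports).  Action modes are recorded on the network for the later
    virtual-target construction; only generic ``binding`` nodes exist at
    this point.  ``active_drug_set`` starts as all drugs.
    """
    net = StudyNetwork()

    dt = _read_tsv(drug_target_path, ["drug_id", "protein_id"])
    n_raw = len(dt)
    if "confidence" in dt.columns:
        conf = pd.to_numeric(dt["confidence"], errors="coerce").fillna(1.0)
        dt = dt[conf >= confidence_cutoff]
        logger.info(
            "drug-target: %d/%d edges pass confidence >= %g",
            len(dt), n_raw, confidence_cutoff,
        )
    n_dup = 0
    for row in dt.itertuples(index=False):
        d, p = row.drug_id, row.protein_id
        net.drugs.setdefault(d, DrugRecord(d))
        node = TargetNode(p, "binding")
        net.targets.setdefault(node.key, node)
        binders = net.target_drugs.setdefault(node.key, set())
        if d in binders:
            n_dup += 1
        binders.add(d)
        mode = getattr(row, "mode", None)
        if isinstance(mode, str) and mode.strip():
            canon = MODE_ALIASES.get(mode.strip().lower())
            if canon is None:
                logger.warning("unknown action mode %r for (%s, %s); ignored", mode, d, p)
            else:
                net.mode_annotations.setdefault((d, p), set()).add(canon)
    if n_dup:
        logger.info("drug-target: %d duplicate edges collapsed", n_dup)

    ds = _read_tsv(drug_se_path, ["drug_id", "se_id"])
    n_dup = 0
    for row in ds.itertuples(index=False):
        d, s = row.drug_id, row.se_id
        net.drugs.setdefault(d, DrugRecord(d))
        net.side_effects.setdefault(s, SideEffectTerm(s))
        elicitors = net.se_drugs.setdefault(s, set())
        if d in elicitors:
            n_dup += 1
        elicitors.add(d)
    if n_dup:
        logger.info("drug-side-effect: %d duplicate edges collapsed", n_dup)

    net.active_drug_set = set(net.drugs)
    net.validate()
    return net


def _parse_bits(text: str, drug_id: str):
    """Parse a fingerprint string: either 0/1 characters or hexadecimal.

    The leftmost character encodes the lowest-index bits.
    """
    text = text.strip()
    if set(text) <= {"0", "1"} and len(text) > 2:
        bits = frozenset(i for i, ch in enumerate(text) if ch == "1")
        return bits, len(text)
    try:
        nibbles = [int(ch, 16) for ch in text.lower()]
    except ValueError as exc:
        raise ValueError(f"fingerprint for {drug_id}: unknown characters in {text!r}") from exc
    bits = set()
    for i, nib in enumerate(nibbles):
        for b in range(4):
            if nib & (1 << b):
                bits.add(4 * i + b)
    return frozenset(bits), 4 * len(text)


def read_fingerprints(path) -> dict:
    """Read a fingerprint table mapping drug_id to a fixed-length bit vector.

    All rows must decode to the same bit length.
    """
    df = _read_tsv(path, ["drug_id", "fingerprint"])
    out: dict = {}
    length = None
    for row in df.itertuples(index=False):
        bits, n = _parse_bits(row.fingerprint, row.drug_id)
        if length is None:
            length = n
        elif n != length:
            raise ValueError(
                f"fingerprint for {row.drug_id} has length {n}, expected {length}"
            )
        out[row.drug_id] = Fingerprint(row.drug_id, bits, n)
    return out


_ANNOTATION_KINDS = (
    "main_targets",
    "family_counts",
    "metabolizing",
    "known_causal",
    "ko_reference",
    "phenotype_synonyms",
)


def read_annotations(paths: Mapping[str, object]) -> AnnotationBundle:
    """Read the optional annotation tables into one bundle.

    ``paths`` maps a kind name (``main_targets``, ``family_counts``,
    ``metabolizing``, ``known_causal``, ``ko_reference``,
    ``phenotype_synonyms``) to a file path; absent or None entries yield
    empty components.  Malformed rows are skipped with a logged count.
    """
    bundle = AnnotationBundle()

    def _rows(kind, cols):
        path = paths.get(kind)
        if path is None or not Path(path).exists():
            return []
        df = _read_tsv(path, cols)
        good, bad = [], 0
        for row in df.itertuples(index=False):
            vals = [getattr(row, c) for c in cols]
            if any(pd.isna(v) or v == "" for v in vals):
                bad += 1
                continue
            good.append(vals)
        if bad:
            logger.warning("%s: skipped %d malformed rows", kind, bad)
        return good

    for d, p in _rows("main_targets", ["drug_id", "protein_id"]):
        bundle.main_targets.setdefault(d, set()).add(p)
    for p, fam, cnt in _rows("family_counts", ["protein_id", "family", "count"]):
        try:
            n = int(cnt)
        except ValueError:
            logger.warning("family_counts: non-integer count %r skipped", cnt)
            continue
        if n < 0:
            raise ValueError(f"family_counts: negative count for {p}/{fam}")
        bundle.family_counts.setdefault(p, {})[fam] = n
    for (p,) in _rows("metabolizing", ["protein_id"]):
        bundle.metabolizing.add(p)
    for p, s in _rows("known_causal", ["protein_id", "se_id"]):
        bundle.known_causal.add((p, s))
    for p, ph in _rows("ko_reference", ["protein_id", "phenotype"]):
        bundle.ko_reference.add((p, ph))
    for ph, s in _rows("phenotype_synonyms", ["phenotype", "se_id"]):
        bundle.phenotype_synonyms[ph] = s
    return bundle


# ---------------------------------------------------------------------------
# prediction table round trip

PREDICTION_COLUMNS = [
    "target_id", "mode", "members", "se_id",
    "a", "b", "c", "d", "p", "q", "excluded", "cluster_id",
]


def write_predictions(records, path) -> None:
    """Write prediction records as TSV with full numeric precision."""
    rows = []
    for r in records:
        rows.append({
            "target_id": r.target.protein_id,
            "mode": r.target.mode,
            "members": ";".join(
                f"{p}:{m}" for p, m in sorted(r.target.merged_members)
            ),
            "se_id": r.se_id,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "p": repr(r.p), "q": repr(r.q),
            "excluded": int(r.excluded),
            "cluster_id": "" if r.cluster_id is None else r.cluster_id,
        })
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_predictions(path):
    """Read a prediction table written by :func:`write_predictions`.

    Extra columns are ignored (and logged); the round trip is exact.
    """
    from .enrichment import ContingencyTable, PredictionRecord

    df = _read_tsv(path, PREDICTION_COLUMNS)
    extra = [c for c in df.columns if c not in PREDICTION_COLUMNS]
    if extra:
        logger.info("read_predictions: ignoring extra columns %s", extra)
    records = []
    for row in df.itertuples(index=False):
        members = frozenset(
            tuple(part.split(":")) for part in row.members.split(";")
        )
        node = TargetNode(row.target_id, row.mode, members)
        table = ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d))
        cluster = row.cluster_id
        cluster_id = None if pd.isna(cluster) or cluster == "" else str(cluster)
        records.append(
            PredictionRecord(
                target=node, se_id=row.se_id, table=table,
                p=float(row.p), q=float(row.q),
                excluded=bool(int(row.excluded)), cluster_id=cluster_id,
            )
        )
    return records


# ---------------------------------------------------------------------------
# orchestration


DEFAULT_CONFIG = {
    "confidence_cutoff": 0.5,
    "tanimoto_cutoff": 0.7,
    "min_support": 5,
    "q_cutoff": 0.01,
    "q_cutoff_strict": 1e-5,
    "cobinding_threshold": 0.5,
    "qvalue_method": "storey-smoother",
    "ks_permutations": 10000,
    "seed": 0,
}


@dataclass
class PipelineResult:
    network: StudyNetwork
    predictions: list
    clusters: list
    benchmark: object  # BenchmarkReport or None
    explanation: object  # pandas DataFrame or None
    stage_counts: dict


def run_pipeline(config: Mapping) -> PipelineResult:
    """Run the full attribution pipeline from flat-file inputs.

    Stages, in order: read tables, build virtual mode targets, drug
    de-redundancy (Hobohm over Tanimoto similarity), merge targets with
    identical active-drug sets, minimum-support filter, enrichment testing
    with q-values, metabolizing-enzyme flagging, co-binding clustering,
    knockout benchmark (when a reference is configured), and per-drug
    explanation summary.  Counts are logged per stage and returned.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    inputs = cfg.get("inputs", {})
    for required in ("drug_target", "drug_se"):
        if required not in inputs:
            raise ValueError(f"stage read: config missing input path {required!r}")

    net = read_network_tables(
        inputs["drug_target"], inputs["drug_se"], cfg["confidence_cutoff"]
    )
    fingerprints = {}
    if inputs.get("fingerprints"):
        fingerprints = read_fingerprints(inputs["fingerprints"])
    annotations = read_annotations(inputs.get("annotations", {}))
    return run_study(net, fingerprints, annotations, cfg)


def run_study(
    network: StudyNetwork,
    fingerprints: Mapping,
    annotations: AnnotationBundle,
    config: Optional[Mapping] = None,
) -> PipelineResult:
    """Run all pipeline stages on an in-memory network (see run_pipeline)."""
    from . import preprocess, enrichment, clustering, benchmark, explain

    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})

    counts: dict = {}
    net = network
    counts["read"] = {
        "drugs": len(net.drugs),
        "targets": len(net.targets),
        "side_effects": len(net.side_effects),
    }

    net = preprocess.build_virtual_targets(net)
    counts["virtual_targets"] = {"targets": len(net.targets)}

    kept = preprocess.hobohm_reduce(
        set(net.drugs), fingerprints, cfg["tanimoto_cutoff"]
    )
    net.active_drug_set = kept
    counts["deredundancy"] = {"drugs": len(kept)}

    net, merge_map = preprocess.merge_equivalent_targets(net)
    counts["merge"] = {"targets": len(net.targets)}

    net = preprocess.filter_min_support(net, cfg["min_support"])
    counts["min_support"] = {
        "targets": len(net.targets),
        "side_effects": len(net.side_effects),
    }

    records = enrichment.run_enrichment(net, method=cfg["qvalue_method"])
    counts["enrichment"] = {"tested_pairs": len(records)}

    preprocess.flag_metabolizing_exclusions(records, annotations.metabolizing)
    significant = enrichment.select_significant(records, cfg["q_cutoff"])
    counts["significant"] = {"pairs": len(significant)}

    clusters = clustering.cluster_predictions(
        records, net, annotations.known_causal,
        q_cutoff=cfg["q_cutoff"], threshold=cfg["cobinding_threshold"],
    )
    counts["clusters"] = {"significant_clusters": len(clusters)}

    report = None
    if annotations.ko_reference:
        reference = benchmark.map_ko_phenotypes(
            annotations.ko_reference, annotations.phenotype_synonyms
        )
        report = benchmark.benchmark_predictions(
            records, net, reference, annotations.known_causal,
            q_cutoff=cfg["q_cutoff"],
            cobinding_threshold=cfg["cobinding_threshold"],
            n_permutations=cfg["ks_permutations"],
            seed=cfg["seed"],
        )
        counts["benchmark"] = {
            "reference_pairs": len(reference.pairs),
            "matched_significant": report.matched_significant,
        }

    summary = explain.summarize_explained_fractions(net, records, annotations)
    counts["explained"] = {"pairs_considered": int(summary.attrs.get("n_pairs", 0))}

    for stage, stats in counts.items():
        logger.info("stage %s: %s", stage, stats)

    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_predictions(records, out / "predictions.tsv")
        clustering.write_clusters(clusters, out / "clusters.tsv")
        _write_merge_map(merge_map, out / "merge_map.tsv")
        if report is not None:
            benchmark.write_report(report, out / "benchmark.tsv")
        summary.to_csv(out / "explanation_summary.tsv", sep="\t", index=False)

    return PipelineResult(
        network=net, predictions=records, clusters=clusters,
        benchmark=report, explanation=summary, stage_counts=counts,
    )


def _write_merge_map(merge_map, path) -> None:
    rows = [
        {"merged_id": key, "members": ";".join(sorted(members))}
        for key, members in sorted(merge_map.items())
    ]
    pd.DataFrame(rows, columns=["merged_id", "members"]).to_csv(
        path, sep="\t", index=False
    )
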