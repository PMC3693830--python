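"""Attribute observed drug-side-effect pairs to predicted causal targets.

Once causal protein-side-effect relations are predicted, each observed
drug-side-effect pair can be explained by looking for significant causal
targets among the drug's own targets, and classified by whether the
explanation runs through the drug's main (therapeutic) target, an
off-target, both, or neither.  Contributions are further broken down by
protein family (GPCR, nuclear receptor, ion channel, kinase, enzyme).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .data_io import AnnotationBundle, StudyNetwork

#: Canonical family labels in tie-break precedence order; ``other`` is the
#: catch-all for unannotated proteins.
FAMILIES = ("GPCR", "nuclear receptor", "ion channel", "kinase", "enzyme", "other")

CATEGORIES = ("main_only", "both", "off_only", "unexplained")


@dataclass
class ExplanationRecord:
    drug_id: str
    se_id: str
    explaining: list  # TargetNode
    category: str
    families: set  # family labels of explaining proteins

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "unexplained") != (not self.explaining):
            raise ValueError("category inconsistent with explaining set")


def classify_family(protein_id: str, family_counts: Mapping) -> str:
    """Assign one family per protein from annotation counts.

    The family with the largest count wins; ties are broken by the fixed
    precedence GPCR > nuclear receptor > ion channel > kinase > enzyme >
    other.  Proteins without counts are ``other``.
    """
    counts = family_counts.get(protein_id) or {}
    best, best_count = "other", -1
    for family in FAMILIES:
        n = counts.get(family, 0)
        if n > best_count:
            best, best_count = family, n
    if best_count <= 0:
        return "other"
    return best


def resolve_main_targets(
    drug_id: str, annotations: AnnotationBundle, family_of: Optional[Mapping] = None
) -> set:
    """Main targets of a drug after dropping large-family blanket annotations.

    Candidates belonging to a family with 10 or more members within the
    drug's own candidate list are removed, so that e.g. a kinase inhibitor
    annotated against the whole kinome keeps only its specific targets.
    """
    candidates = annotations.main_targets.get(drug_id, set())
    if not candidates:
        return set()
    if family_of is None:
        family_of = {
            p: classify_family(p, annotations.family_counts) for p in candidates
        }
    sizes: dict = {}
    for p in candidates:
        fam = family_of.get(p, "other")
        sizes[fam] = sizes.get(fam, 0) + 1
    return {p for p in candidates if sizes[family_of.get(p, "other")] < 10}


def explain_pair(
    drug_id: str,
    se_id: str,
    significant_predictions,
    network: StudyNetwork,
    main_targets: set,
    family_of: Optional[Mapping] = None,
) -> ExplanationRecord:
    """Explain one observed drug-side-effect pair.

    The explaining set consists of the significant target nodes for this
    side effect that the drug binds with a compatible action mode.  Mode
    compatibility is encoded in the virtual-node edges themselves: an
    edge to an activation/inhibition node exists only for drugs annotated
    with that mode, while generic binding nodes match any binder.  The
    category compares the explaining proteins with the drug's resolved
    main targets.
    """
    if drug_id not in network.drugs:
        raise KeyError(f"unknown drug {drug_id}")
    if se_id not in network.side_effects:
        raise KeyError(f"unknown side effect {se_id}")

    explaining = [
        r.target
        for r in significant_predictions
        if r.se_id == se_id and drug_id in network.target_drugs.get(r.target.key, ())
    ]
    proteins = set().union(*(t.base_proteins for t in explaining)) if explaining else set()
    has_main = bool(proteins & main_targets)
    has_off = bool(proteins - main_targets)
    if not explaining:
        category = "unexplained"
    elif has_main and has_off:
        category = "both"
    elif has_main:
        category = "main_only"
    else:
        category = "off_only"

    families = set()
    if family_of is not None:
        families = {family_of.get(p, "other") for p in proteins}
    return ExplanationRecord(drug_id, se_id, explaining, category, families)


def explain_observed_pairs(
    network: StudyNetwork,
    predictions,
    annotations: AnnotationBundle,
    q_cutoff: float = 0.01,
):
    """Explain every observed drug-side-effect edge whose side effect has
    at least one significant causal prediction.

    Uses the FULL drug set: drugs removed as chemically redundant still
    have observed side effects to explain.  Returns (explanations,
    family_of, main_targets_by_drug).
    """
    from .enrichment import select_significant

    significant = select_significant(predictions, q_cutoff)
    explained_ses = {r.se_id for r in significant}

    family_of = {
        p: classify_family(p, annotations.family_counts)
        for p in {p for t in network.targets.values() for p in t.base_proteins}
        | set(annotations.family_counts)
    }
    main_cache = {
        d: resolve_main_targets(d, annotations, family_of) for d in network.drugs
    }

    explanations = []
    for se_id, drugs in sorted(network.se_drugs.items()):
        if se_id not in explained_ses:
            continue
        for drug_id in sorted(drugs):
            explanations.append(
                explain_pair(
                    drug_id, se_id, significant, network,
                    main_cache[drug_id], family_of,
                )
            )
    return explanations, family_of, main_cache


def explained_fraction(explanations, families=None) -> float:
    """Fraction of pairs explained by a protein of one of ``families``.

    ``families=None`` places no family restriction.  Grows monotonically
    with the family set, since each added family can only add explaining
    proteins.
    """
    if not explanations:
        return float("nan")
    if families is None:
        k = sum(e.category != "unexplained" for e in explanations)
    else:
        k = sum(bool(e.families & set(families)) for e in explanations)
    return k / len(explanations)


def summarize_explained_fractions(
    network: StudyNetwork,
    predictions,
    annotations: AnnotationBundle,
    q_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Fractions of observed drug-side-effect pairs explained, three ways.

    Considers every observed drug-side-effect edge whose side effect has
    at least one significant causal prediction, using the FULL drug set
    (drugs removed as chemically redundant still have observed side
    effects to explain).  Returns a long-form table with three blocks:

    * ``category`` — main_only / both / off_only / unexplained fractions,
      over pairs of drugs with a non-empty resolved main-target set;
    * ``family`` — fraction of pairs explained by at least one protein of
      each family, over all considered pairs;
    * ``drug_family`` — fraction explained, grouped by the drug's most
      prevalent main-target family.

    Denominators are reported alongside each fraction.
    """
    explanations, family_of, main_cache = explain_observed_pairs(
        network, predictions, annotations, q_cutoff
    )

    rows = []
    n_pairs = len(explanations)

    with_main = [e for e in explanations if main_cache[e.drug_id]]
    n_main = len(with_main)
    for category in CATEGORIES:
        k = sum(e.category == category for e in with_main)
        rows.append({
            "block": "category", "key": category,
            "fraction": k / n_main if n_main else float("nan"),
            "count": k, "denominator": n_main,
        })

    for family in FAMILIES:
        k = sum(family in e.families for e in explanations)
        rows.append({
            "block": "family", "key": family,
            "fraction": k / n_pairs if n_pairs else float("nan"),
            "count": k, "denominator": n_pairs,
        })

    def prevalent_family(drug_id: str) -> Optional[str]:
        mains = main_cache[drug_id]
        if not mains:
            return None
        tally: dict = {}
        for p in mains:
            fam = family_of.get(p, "other")
            tally[fam] = tally.get(fam, 0) + 1
        best = max(tally.values())
        return next(f for f in FAMILIES if tally.get(f, 0) == best)

    by_drug_family: dict = {}
    for e in explanations:
        fam = prevalent_family(e.drug_id)
        if fam is None:
            continue
        total, expl, within = by_drug_family.get(fam, (0, 0, 0))
        explained = e.category != "unexplained"
        by_drug_family[fam] = (
            total + 1,
            expl + int(explained),
            within + int(explained and fam in e.families),
        )
    for family in FAMILIES:
        total, expl, within = by_drug_family.get(family, (0, 0, 0))
        rows.append({
            "block": "drug_family", "key": family,
            "fraction": expl / total if total else float("nan"),
            "count": expl, "denominator": total,
        })
        rows.append({
            "block": "drug_family_within", "key": family,
            "fraction": within / total if total else float("nan"),
            "count": within, "denominator": total,
        })

    df = pd.DataFrame(rows, columns=["block", "key", "fraction", "count", "denominator"])
    df.attrs["n_pairs"] = n_pairs
    return df
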