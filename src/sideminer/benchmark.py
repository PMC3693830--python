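"""Validation of predictions against independent protein-side-effect pairs.

Two complementary checks: (1) the q-values of reference pairs (from
literature surveys or mouse-knockout phenotypes mapped to human side
effects) should be shifted toward zero relative to the background of all
tested pairs — quantified with a one-sided two-sample Kolmogorov-Smirnov
test whose p-value is obtained by label permutation; (2) significant
co-binding clusters should match reference pairs more often than clusters
overall — quantified with a one-sided Fisher exact test on the 2x2
cluster-match table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .enrichment import ContingencyTable, fisher_greater


@dataclass
class ReferencePairSet:
    """Independent (protein, side effect) pairs used for validation.

    Proteins are referenced by base protein id; action-mode variants of a
    prediction all count toward the same base pair.
    """

    pairs: set  # {(protein_id, term_id)}
    source: str = "reference"


@dataclass
class BenchmarkReport:
    source: str
    d_plus: float
    ks_p_perm: float
    ks_p_asymptotic: float
    n_reference: int
    n_background: int
    match_table: Optional[ContingencyTable] = None
    match_p: float = float("nan")
    matched_significant: int = 0
    total_significant: int = 0
    matched_all: int = 0
    total_all: int = 0
    notes: dict = field(default_factory=dict)


def map_ko_phenotypes(ko_reference: set, phenotype_synonyms: Mapping) -> ReferencePairSet:
    """Map knockout gene-phenotype pairs onto side-effect terms.

    Only phenotypes with an exact synonym entry contribute (strict
    matching); unmapped phenotypes are skipped and counted.  Output pairs
    are deduplicated.
    """
    import logging

    pairs = set()
    skipped = 0
    for protein, phenotype in ko_reference:
        term = phenotype_synonyms.get(phenotype)
        if term is None:
            skipped += 1
            continue
        pairs.add((protein, term))
    if skipped:
        logging.getLogger("sideminer").info(
            "ko mapping: %d phenotypes without synonym skipped", skipped
        )
    return ReferencePairSet(pairs=pairs, source="mouse-knockout")


def collapse_best_q(predictions) -> dict:
    """Best (smallest) q per base (protein, side effect) pair.

    Mode-specific virtual nodes and merged nodes are expanded to their
    base proteins; each base pair keeps the minimum q over all node
    variants covering it.
    """
    best: dict = {}
    for r in predictions:
        for protein in r.target.base_proteins:
            key = (protein, r.se_id)
            if r.q < best.get(key, np.inf):
                best[key] = r.q
    return best


def _d_plus(ref: np.ndarray, bg: np.ndarray) -> float:
    """sup_x [F_ref(x) - F_bg(x)] for two empirical CDFs."""
    pooled = np.concatenate([ref, bg])
    labels = np.concatenate([np.ones(ref.size, bool), np.zeros(bg.size, bool)])
    order = np.argsort(pooled, kind="mergesort")
    pooled, labels = pooled[order], labels[order]
    cum_ref = np.cumsum(labels) / ref.size
    cum_bg = np.cumsum(~labels) / bg.size
    diff = cum_ref - cum_bg
    # with ties, the CDF difference is well-defined only at the end of a
    # run of equal values
    last_of_run = np.ones(pooled.size, bool)
    last_of_run[:-1] = pooled[:-1] != pooled[1:]
    return float(max(0.0, diff[last_of_run].max()))


def ks_one_sided(
    reference_qs,
    background_qs,
    n_permutations: int = 100_000,
    seed: int = 0,
):
    """One-sided two-sample KS test (reference stochastically smaller).

    Returns (D+, permutation p, asymptotic p).  D+ is the maximal excess
    of the reference CDF over the background CDF.  The permutation p is
    computed from label shuffles of the pooled sample; when the number of
    distinct splits C(m+n, m) does not exceed ``n_permutations`` the
    enumeration is exhaustive and the p-value exact.  The asymptotic
    one-sided tail exp(-2 D+^2 mn/(m+n)) is reported alongside.
    """
    ref = np.asarray(reference_qs, dtype=float)
    bg = np.asarray(background_qs, dtype=float)
    if ref.size == 0 or bg.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = ref.size, bg.size
    d_obs = _d_plus(ref, bg)

    pooled = np.concatenate([ref, bg])
    total = comb(m + n, m)
    if total <= n_permutations:
        count = 0
        idx_all = range(m + n)
        for ref_idx in combinations(idx_all, m):
            mask = np.zeros(m + n, bool)
            mask[list(ref_idx)] = True
            if _d_plus(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
                count += 1
        p_perm = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(m + n)
            if _d_plus(pooled[perm[:m]], pooled[perm[m:]]) >= d_obs - 1e-12:
                count += 1
        p_perm = (count + 1) / (n_permutations + 1)

    p_asym = float(np.exp(-2.0 * d_obs**2 * m * n / (m + n)))
    return d_obs, p_perm, min(1.0, p_asym)


def _cluster_matches(cluster, reference: ReferencePairSet) -> bool:
    """A cluster matches when any member protein forms a reference pair
    with the cluster's side effect."""
    return any((p, cluster.se_id) in reference.pairs for p in cluster.base_proteins)


def match_rate_fisher(clusters_at_cutoff, all_clusters, reference: ReferencePairSet):
    """Enrichment of reference matches among significant clusters.

    2x2 over clusters: [matched, unmatched] x [significant,
    non-significant], where the non-significant margin is the remainder of
    all clusters after removing the significant ones; tested one-sided for
    enrichment.  Returns (table, p, matched_significant, matched_all).
    """
    matched_sig = sum(_cluster_matches(c, reference) for c in clusters_at_cutoff)
    matched_all = sum(_cluster_matches(c, reference) for c in all_clusters)
    n_sig = len(clusters_at_cutoff)
    n_all = len(all_clusters)
    table = ContingencyTable(
        matched_sig,
        n_sig - matched_sig,
        matched_all - matched_sig,
        (n_all - n_sig) - (matched_all - matched_sig),
    )
    return table, fisher_greater(table), matched_sig, matched_all


def benchmark_predictions(
    records,
    network,
    reference: ReferencePairSet,
    known_causal: set = frozenset(),
    q_cutoff: float = 0.01,
    cobinding_threshold: float = 0.5,
    n_permutations: int = 10_000,
    seed: int = 0,
    counting_unit: str = "cluster",
) -> BenchmarkReport:
    """Full benchmark: q-value shift (KS) plus cluster match-rate Fisher.

    ``counting_unit='pair'`` reproduces the unclustered variant in which
    each base (protein, side effect) pair counts individually.
    """
    from .clustering import cluster_predictions

    best_q = collapse_best_q(r for r in records if not r.excluded)
    ref_qs = [q for (pair, q) in best_q.items() if pair in reference.pairs]
    bg_qs = [q for (pair, q) in best_q.items() if pair not in reference.pairs]
    if not ref_qs:
        raise ValueError("no reference pair overlaps the tested universe")
    d_plus, p_perm, p_asym = ks_one_sided(
        ref_qs, bg_qs, n_permutations=n_permutations, seed=seed
    )

    report = BenchmarkReport(
        source=reference.source,
        d_plus=d_plus, ks_p_perm=p_perm, ks_p_asymptotic=p_asym,
        n_reference=len(ref_qs), n_background=len(bg_qs),
    )

    if counting_unit == "cluster":
        all_clusters = cluster_predictions(
            records, network, known_causal,
            q_cutoff=np.inf, threshold=cobinding_threshold,
        )
        # run the significant cutoff last so records keep its cluster ids
        sig_clusters = cluster_predictions(
            records, network, known_causal,
            q_cutoff=q_cutoff, threshold=cobinding_threshold,
        )
        table, p, matched_sig, matched_all = match_rate_fisher(
            sig_clusters, all_clusters, reference
        )
        report.total_significant = len(sig_clusters)
        report.total_all = len(all_clusters)
    elif counting_unit == "pair":
        sig_pairs = {
            pair for pair, q in best_q.items() if q < q_cutoff
        }
        all_pairs = set(best_q)
        matched_sig = sum(pair in reference.pairs for pair in sig_pairs)
        matched_all = sum(pair in reference.pairs for pair in all_pairs)
        table = ContingencyTable(
            matched_sig,
            len(sig_pairs) - matched_sig,
            matched_all - matched_sig,
            len(all_pairs) - len(sig_pairs) - (matched_all - matched_sig),
        )
        p = fisher_greater(table)
        report.total_significant = len(sig_pairs)
        report.total_all = len(all_pairs)
    else:
        raise ValueError(f"unknown counting unit {counting_unit!r}")

    report.match_table = table
    report.match_p = p
    report.matched_significant = matched_sig
    report.matched_all = matched_all
    return report


def write_report(report: BenchmarkReport, path) -> None:
    row = {
        "source": report.source,
        "d_plus": repr(report.d_plus),
        "ks_p_perm": repr(report.ks_p_perm),
        "ks_p_asymptotic": repr(report.ks_p_asymptotic),
        "n_reference": report.n_reference,
        "n_background": report.n_background,
        "matched_significant": report.matched_significant,
        "total_significant": report.total_significant,
        "matched_all": report.matched_all,
        "total_all": report.total_all,
        "match_p": repr(report.match_p),
    }
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


def format_report(report: BenchmarkReport) -> str:
    lines = [
        f"Benchmark against {report.source}:",
        f"  q-value shift: D+ = {report.d_plus:.3f}, permutation p = {report.ks_p_perm:.3g} "
        f"(asymptotic {report.ks_p_asymptotic:.3g}); "
        f"{report.n_reference} reference vs {report.n_background} background pairs",
        f"  match rate: {report.matched_significant}/{report.total_significant} significant "
        f"clusters matched vs {report.matched_all}/{report.total_all} overall; "
        f"Fisher p = {report.match_p:.3g}",
    ]
    return "\n".join(lines)
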