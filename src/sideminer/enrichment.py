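"""Overrepresentation testing of target-side-effect pairs and FDR control.

For every (target node, side effect) pair we count, over the non-redundant
drug set, the drugs that bind the target, that elicit the side effect,
that do both and that do neither, and test overrepresentation of the joint
count with a one-sided Fisher exact test.  The resulting p-values are
converted to q-values (minimum false discovery rate at which the pair
would be called significant) with a Storey-type pi0 estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.special import gammaln, logsumexp

from .data_io import StudyNetwork, TargetNode


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug counts for one target-side-effect pair.

    a: binds target and elicits side effect; b: binds only;
    c: elicits only; d: neither.  All counts over the active drug set.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_binders(self) -> int:
        return self.a + self.b

    @property
    def n_elicitors(self) -> int:
        return self.a + self.c


@dataclass
class PredictionRecord:
    """One tested target-side-effect pair with its statistics."""

    target: TargetNode
    se_id: str
    table: ContingencyTable
    p: float
    q: float = float("nan")
    excluded: bool = False
    cluster_id: Optional[str] = None


def contingency_table(target_key: str, se_id: str, network: StudyNetwork) -> ContingencyTable:
    """Count the 2x2 drug table for one pair over the active drug set."""
    if target_key not in network.targets:
        raise KeyError(f"unknown target {target_key}")
    if se_id not in network.side_effects:
        raise KeyError(f"unknown side effect {se_id}")
    active = network.active_drug_set
    binders = network.target_drugs.get(target_key, set()) & active
    elicitors = network.se_drugs.get(se_id, set()) & active
    a = len(binders & elicitors)
    b = len(binders) - a
    c = len(elicitors) - a
    d = len(active) - a - b - c
    return ContingencyTable(a, b, c, d)


def _log_pmf(a, k_total, n_draw, n_total):
    """log hypergeometric pmf: a successes among n_draw draws from a pool
    of n_total with k_total successes.  Arguments may be numpy arrays."""
    return (
        gammaln(k_total + 1) - gammaln(a + 1) - gammaln(k_total - a + 1)
        + gammaln(n_total - k_total + 1)
        - gammaln(n_draw - a + 1) - gammaln(n_total - k_total - n_draw + a + 1)
        - (gammaln(n_total + 1) - gammaln(n_draw + 1) - gammaln(n_total - n_draw + 1))
    )


def fisher_greater(table: ContingencyTable) -> float:
    """One-sided Fisher exact p-value for overrepresentation, P(X >= a).

    The upper hypergeometric tail with both margins fixed, accumulated in
    log-space via log-gamma for numerical stability; no continuity
    correction.
    """
    a, n = table.a, table.n
    k, m = table.n_elicitors, table.n_binders
    hi = min(k, m)
    if a <= max(0, k + m - n):
        return 1.0
    support = np.arange(a, hi + 1)
    if support.size == 0:
        return 1.0
    logp = _log_pmf(support, k, m, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def fisher_greater_many(a, n_binders, n_elicitors, n_total) -> np.ndarray:
    """Vectorised one-sided Fisher tails for arrays of 2x2 margins.

    Same statistic as :func:`fisher_greater`, computed for many pairs at
    once by padding the tail supports to a common length.
    """
    a = np.asarray(a, dtype=np.int64)
    m = np.asarray(n_binders, dtype=np.int64)
    k = np.asarray(n_elicitors, dtype=np.int64)
    hi = np.minimum(m, k)
    width = int(np.max(hi - a, initial=-1)) + 1
    if width <= 0:
        return np.ones_like(a, dtype=float)
    offsets = np.arange(width)
    support = a[:, None] + offsets[None, :]
    valid = support <= hi[:, None]
    support = np.where(valid, support, 0)
    logp = _log_pmf(support, k[:, None], m[:, None], n_total)
    logp = np.where(valid, logp, -np.inf)
    with np.errstate(over="ignore"):
        tails = np.exp(logsumexp(logp, axis=1))
    return np.minimum(tails, 1.0)


_LAMBDA_GRID = np.arange(0.0, 0.9001, 0.05)
# Upper bound on the smoothing spline's residual sum of squares; large
# enough that with 19 grid points the fit is close to a global cubic,
# which is what stabilises pi0 at the right end of the grid.
_SPLINE_SMOOTHING = 1.0
_MIN_PVALUES_FOR_SMOOTHER = 100
# minimal expected null count #{p > lambda} for a grid point to be usable
# when a discrete null exceedance matrix is supplied
_MIN_NULL_EXPECTATION = 5.0


def null_exceedance_matrix(n_binders, n_elicitors, n_total, lambdas=_LAMBDA_GRID):
    """Null probabilities P0(p > lambda | tested) for discrete Fisher tests.

    The tested universe is conditioned on a >= 1, and the one-sided
    Fisher p-value is discrete, so under the null the attainable p-values
    of a pair stop well short of 1 whenever P(X >= 1) < 1.  For each pair
    the exact null survival of its p-value is computed from the
    hypergeometric tail sequence T_a = P(X >= a):

        P0(p > lambda | tested) = (T_1 - T_{a*}) / T_1,
        a* = min {a : T_a <= lambda}   (T_{a*} = 0 when no such a).

    Returns an (n_pairs, n_lambdas) matrix used as the pi0 denominator in
    place of the uniform-null expectation m (1 - lambda).
    """
    m = np.asarray(n_binders, dtype=np.int64)
    k = np.asarray(n_elicitors, dtype=np.int64)
    hi = np.minimum(m, k)
    width = int(hi.max())
    support = np.arange(1, width + 1)
    valid = support[None, :] <= hi[:, None]
    logp = _log_pmf(np.where(valid, support[None, :], 0), k[:, None], m[:, None], n_total)
    logp = np.where(valid, logp, -np.inf)
    # reverse cumulative logsumexp -> log T_a for a = 1..width
    log_tails = np.logaddexp.accumulate(logp[:, ::-1], axis=1)[:, ::-1]
    tails = np.where(valid, np.minimum(np.exp(log_tails), 1.0), 0.0)
    t1 = tails[:, 0]
    lambdas = np.asarray(lambdas, dtype=float)
    exceed = np.empty((m.size, lambdas.size))
    for j, lam in enumerate(lambdas):
        t_star = np.max(np.where(tails <= lam, tails, 0.0), axis=1)
        exceed[:, j] = np.clip((t1 - t_star) / t1, 0.0, 1.0)
    return exceed


def estimate_qvalues(
    pvalues: Sequence[float],
    method: str = "storey-smoother",
    null_exceedance=None,
):
    """Convert p-values to q-values; returns (qvalues, pi0).

    ``storey-smoother`` estimates the true-null proportion pi0 by
    evaluating pi0(lambda) = #{p > lambda} / E0[#{p > lambda}] on the
    grid lambda = 0, 0.05, ..., 0.90, smoothing with a cubic spline and
    taking the value at the right end of the grid, clipped into (0, 1].
    For continuous p-values the null expectation is m (1 - lambda)
    (Storey's estimator); for discrete truncated tests a
    ``null_exceedance`` matrix from :func:`null_exceedance_matrix`
    replaces it, and grid points whose null expectation falls below 5
    are dropped (the estimate is evaluated at the last usable point).
    With fewer than 100 p-values the estimate is unstable and the method
    falls back to pi0 = 1.  ``bh`` fixes pi0 = 1, reproducing
    Benjamini-Hochberg adjusted p-values exactly.

    q_i = min over p_j >= p_i of pi0 * m * p_j / rank_j, clipped to [0,1];
    q is monotone non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey-smoother", "bh"):
        raise ValueError(f"unknown method {method!r}")

    m = p.size
    if method == "bh" or m < _MIN_PVALUES_FOR_SMOOTHER:
        pi0 = 1.0
    else:
        counts = np.array([np.sum(p > lam) for lam in _LAMBDA_GRID], dtype=float)
        if null_exceedance is None:
            expected = m * (1.0 - _LAMBDA_GRID)
            usable = np.ones_like(_LAMBDA_GRID, dtype=bool)
        else:
            expected = np.asarray(null_exceedance).sum(axis=0)
            usable = expected >= _MIN_NULL_EXPECTATION
        if usable.sum() < 4:  # not enough points for a cubic fit
            pi0 = 1.0
        else:
            grid = _LAMBDA_GRID[usable]
            pi0_lambda = counts[usable] / expected[usable]
            spline = UnivariateSpline(grid, pi0_lambda, k=3, s=_SPLINE_SMOOTHING)
            pi0 = float(spline(grid[-1]))
            pi0 = min(1.0, max(pi0, 1.0 / m))  # clip into (0, 1]

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def run_enrichment(network: StudyNetwork, method: str = "storey-smoother"):
    """Test every pair with at least one co-annotated drug.

    Pairs where no drug both binds the target and elicits the side effect
    (a = 0) are not tested — for over half of all possible pairs no drug
    carries both annotations — and q-values are computed jointly over the
    tested universe only.  Records are returned sorted by q then p.
    """
    target_keys = sorted(network.targets)
    se_ids = sorted(network.side_effects)
    if not target_keys or not se_ids:
        raise ValueError("no testable pairs: empty target or side-effect set")

    active = sorted(network.active_drug_set)
    drug_index = {d: i for i, d in enumerate(active)}
    n_total = len(active)

    t_mat = np.zeros((len(target_keys), n_total), dtype=bool)
    for i, key in enumerate(target_keys):
        for d in network.target_drugs.get(key, ()):
            j = drug_index.get(d)
            if j is not None:
                t_mat[i, j] = True
    s_mat = np.zeros((len(se_ids), n_total), dtype=bool)
    for i, term in enumerate(se_ids):
        for d in network.se_drugs.get(term, ()):
            j = drug_index.get(d)
            if j is not None:
                s_mat[i, j] = True

    a_mat = t_mat.astype(np.int64) @ s_mat.T.astype(np.int64)
    n_binders = t_mat.sum(axis=1)
    n_elicitors = s_mat.sum(axis=1)

    t_idx, s_idx = np.nonzero(a_mat)
    if t_idx.size == 0:
        raise ValueError("no testable pairs: no target-side-effect co-annotation")
    a = a_mat[t_idx, s_idx]
    m = n_binders[t_idx]
    k = n_elicitors[s_idx]
    pvals = fisher_greater_many(a, m, k, n_total)
    exceed = None
    if method == "storey-smoother" and t_idx.size >= _MIN_PVALUES_FOR_SMOOTHER:
        exceed = null_exceedance_matrix(m, k, n_total)
    qvals, _pi0 = estimate_qvalues(pvals, method=method, null_exceedance=exceed)

    records = []
    for idx in range(t_idx.size):
        ti, si = int(t_idx[idx]), int(s_idx[idx])
        ai, mi, ki = int(a[idx]), int(m[idx]), int(k[idx])
        table = ContingencyTable(ai, mi - ai, ki - ai, n_total - mi - ki + ai)
        records.append(
            PredictionRecord(
                target=network.targets[target_keys[ti]],
                se_id=se_ids[si],
                table=table,
                p=float(pvals[idx]),
                q=float(qvals[idx]),
            )
        )
    records.sort(key=lambda r: (r.q, r.p, r.target.key, r.se_id))
    return records


def select_significant(records, q_cutoff: float = 0.01):
    """Records with q strictly below the cutoff, metabolizing flags excluded."""
    return [r for r in records if r.q < q_cutoff and not r.excluded]
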