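# Methods

## Model

The pipeline assumes a simple causal structure: perturbing certain proteins
(in a certain direction — activation or inhibition) elicits certain side
effects, independently of which drug does the perturbing. Observed
drug–side-effect labels are then a noisy readout of the drug's target
profile: a drug carries a side effect if it perturbs a causal protein for
it (with some penetrance) or through unrelated background causes. Under
this model a causal (protein, side effect) pair shows up as an
overrepresentation of the side effect among the protein's binders, which is
what the Fisher test detects. The method cannot separate proteins bound by
the same drugs (handled by merging and clustering), cannot detect causes of
very common multi-etiology side effects (never sufficiently
overrepresented for any one target), and has no power for proteins bound by
few drugs (removed by the support filter).

## Pipeline stages and parameters

Stage order: read → virtual mode targets → drug de-redundancy → target
merging → minimum-support filter → enrichment → metabolizing flag →
clustering → benchmark → explanation. De-redundancy runs before merging so
that merge signatures are computed over the final counting population (the
active drug set); merging two targets can only depend on drugs that are
actually counted.

| parameter | default | meaning |
|---|---|---|
| confidence cutoff | 0.5 | minimum drug–target confidence score for an edge |
| Tanimoto cutoff | 0.7 | similarity above which two drugs are redundant |
| minimum support | 5 drugs | smallest binder/elicitor count for a testable entity |
| q cutoff | 0.01 (strict 10⁻⁵) | significance threshold on the q-value, strict inequality |
| co-binding threshold | 0.5 | fraction of one target's drugs shared with another for clustering |
| family-size cutoff | 10 | main-target families this large are blanket annotations and dropped |

All cutoffs follow standard practice for these data sources. Drugs removed
by de-redundancy stay in the network: de-redundancy exists to avoid
double-counting evidence in the statistics, but a redundant drug's observed
side effects still need explaining, so the explanation stage uses the full
drug set.

## Statistics

**Fisher tail.** One-sided (overrepresentation) exact hypergeometric tail
P(X ≥ a) with margins fixed, accumulated in log-space via log-gamma; no
continuity correction. A vectorised variant pads tails to a common length
for the ~10⁴ pairs tested per run. Tests cross-check the scalar path
against exact integer enumeration of all same-margin tables (totals ≤ 60,
tolerance 10⁻¹²) and against `scipy.stats.fisher_exact`.

**Tested universe.** Only pairs with a ≥ 1 (at least one drug binding the
target and carrying the side effect) are tested; q-values are computed
jointly over this universe.

**q-values.** π₀ (the true-null proportion) is estimated on the grid
λ = 0, 0.05, …, 0.90 and smoothed with a cubic smoothing spline (fixed
smoothing parameter, evaluated at the right end of the grid, clipped into
(0, 1]); q_i = min_{p_j ≥ p_i} π₀ m p_j / rank_j. With fewer than 100
p-values π₀ falls back to 1 (Benjamini–Hochberg), which the `bh` method
also forces; this reproduces BH adjusted p-values exactly.

The textbook Storey denominator m(1 − λ) assumes null p-values uniform on
[0, 1]. That fails here twice over: the Fisher p-values are discrete, and
the a ≥ 1 conditioning removes exactly the outcomes that would produce
p-values near 1, so almost no null mass lies above λ ≈ 0.7 and the naive
ratio collapses (π₀ ≈ 0.02 on synthetic worlds, inflating the empirical
cluster-level FDR to ~0.6). The enrichment path therefore replaces the
denominator with the exact conditional null expectation
Σ_i P₀(p_i > λ | a_i ≥ 1), computed per pair from its hypergeometric tail
sequence; grid points whose null expectation drops below 5 are discarded
and the spline is evaluated at the last usable point. This reduces to
Storey's estimator for continuous p-values and restores π₀ ≈ 1 on null
worlds. `estimate_qvalues` applies the plain uniform-null formula when no
exceedance matrix is supplied.

**One-sided KS.** D⁺ = sup_x [F_ref(x) − F_bg(x)], evaluated at the end of
each run of tied pooled values. The permutation p-value is exact
(exhaustive over label splits) whenever C(m+n, m) does not exceed the
permutation budget, otherwise Monte Carlo with the add-one correction; the
asymptotic tail exp(−2 D⁺² mn/(m+n)) is reported alongside. Permutation is
primary because reference sets are small (tens of pairs).

**Cluster matching.** Benchmarks count clusters, not proteins: a cluster
matches if any member protein forms a reference pair with the cluster's
side effect (mode-agnostic, merged members expanded), and enrichment of
matches among significant clusters over all clusters is tested one-sided.
The total cluster set includes the significant ones. A pair-level counting
variant is available behind a flag.

## Clustering decisions

The co-binding criterion is directional; an undirected edge is created if
either direction reaches the threshold ("at least half" → ≥ 0.5), and
clusters are connected components (single linkage) — the minimal
deterministic closure of the pairwise rule. When a cluster contains several
known causal proteins, the one whose record has the smallest q becomes the
seed; the others stay ordinary members.

## Explanation decisions

Explanation requires node-level significance: a drug's side effect is
explained only by significant target nodes the drug itself binds (clusters
are not expanded to co-members the drug does not bind). Mode compatibility
is encoded in the virtual-node edges: an edge to an activation/inhibition
node exists only for drugs annotated with that mode, and generic binding
nodes match any binder. Family classification takes the annotation with the
highest count, ties broken by the fixed precedence GPCR > nuclear
receptor > ion channel > kinase > enzyme > other. Category fractions are
reported over drugs with a non-empty resolved main-target set.

## Synthetic worlds

Defaults: 100 proteins in 20 families, 300 drugs (plus 10 near-clones),
in-family binding probability β = 0.8, off-family ε = 0.02, 50 side
effects, 30 planted mode-specific causal pairs with penetrance 0.8,
background label rate 0.05, 70 % of edges mode-annotated (90 % matching the
protein's dominant mode), 128-bit fingerprints built from family prototypes
with 30 % per-bit mutation (near-clones: 2 %), knockout reference with 80 %
sensitivity plus 20 decoys and 2 unmappable phenotypes, 5 metabolizing
proteins, and half of the planted pairs exposed as known causal. Side
effects combine causes by noisy-OR — the simplest generative rule
consistent with the overrepresentation logic. Entity counts are sized so
that per-protein binder counts (~18) and per-side-effect label counts
(~15–25) sit in the regime the support filter and the test are designed
for, while a full pipeline run stays under two seconds; multi-seed
calibration checks use 10–25 seeds for the same reason.

What the generator does **not** emulate: dose–response and affinity
structure, correlated side-effect co-occurrence beyond shared causes,
frequency-stratified labels, polypharmacology beyond one primary family
per drug, and biased reporting. Passing recovery tests therefore shows the
machinery is correct under the stated causal model, not that real-data
attributions at these rates are guaranteed.

At these defaults, cluster-level recall ≥ 0.8 and empirical cluster FDR
≤ 0.05 (averaged over 10 seeds) are asserted as the package's own
acceptance property, and on background-only worlds the mean false-discovery
proportion at q < 0.01 over ≥ 25 seeds must stay within twice the nominal
rate up to the binomial Monte-Carlo error of that estimate (the per-seed
FDP is 0/1 under a global null, so the estimate is compared with its
sampling noise acknowledged rather than as a hard point value).

## Degenerate inputs and tie-breaks

Tanimoto of two all-zero fingerprints is 0 by convention. Drugs without
fingerprints cannot be compared and survive de-redundancy unconditionally
(with a warning). Hobohm ties (equal neighbour counts) remove the
lexicographically greatest drug id, making the reduction deterministic
without randomness; the no-similar-pair post-condition is asserted on every
run. Duplicate edges are collapsed with a logged count; unknown action
modes and annotations referencing absent edges warn and are ignored;
malformed annotation rows are skipped and counted. Empty p-value lists,
out-of-range p-values, empty KS samples and targets with zero active drugs
raise errors.

## Known limitations

Merged targets inherit the union of member edges, so after merging, binder
sets outside the active drug set may mix members. π₀ smoothing uses a fixed
smoothing parameter rather than cross-validation; with heavy signal
(π₀ ≪ 1) the discrete-aware estimate is conservative. The KS permutation
test shuffles labels globally and ignores the dependence between q-values
of overlapping nodes — adequate for benchmarking, not for formal inference
on D⁺. Action modes beyond activation/inhibition (e.g. partial agonism,
allosteric modulation) are not represented.
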