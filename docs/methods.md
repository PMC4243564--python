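# Methods

## Label Bayesian networks

A label Bayesian network (LBN) encodes one neuron's annotator-derived
joint label distribution over the five class variables C1–C5
(cardinalities 2, 2, 2, 4, 10; |Ω| = 320).  LBNs are learned from the
neuron's annotation matrix by search+score structure learning followed by
maximum-likelihood parameter estimation.

**Scores.** Three decomposable scores are implemented, all on the log
scale with higher-is-better orientation:

* BIC: log-likelihood − (log N / 2) · Σᵢ (rᵢ−1)qᵢ, with the convention
  0·log 0 ≡ 0;
* K2: the Cooper–Herskovits marginal likelihood, a Dirichlet(1) prior per
  CPT cell;
* BDe: the likelihood-equivalent Dirichlet marginal likelihood with cell
  hyperparameters ess/(rᵢqᵢ).  The equivalent sample size defaults to
  **ess = 1** (uniform BDeu); it is exposed everywhere the score is.
  BDe is the default score for both LBN learning and consensus learning.

**Search.** Tabu search over single-arc add/delete/reverse moves, starting
from the empty graph, applying the best admissible move each iteration
(worsening moves allowed; recently undone moves are tabu for `tabu_len`
iterations, default 10; an aspiration criterion admits tabu moves that
beat the incumbent).  The search stops after `tabu_len` iterations without
improving the incumbent or at `max_iter` (default 100·d²).  Ties between
equal-score moves are broken in canonical (node-order, arc-lexicographic)
order, so the search is exactly reproducible.  Local scores are memoized
per (child, parent-set): with five variables there are at most 80 of them,
so after one counting pass the search is lookup-bound — this is why the
liberal iteration budget is affordable.

**Parameters.** CPT rows are relative frequencies.  A parent configuration
never observed in the training data receives a uniform row — nothing in
the data constrains it, and the uniform row keeps the network valid; the
fallback is logged.

**Inference.** The 320-state space is enumerated exactly; the joint,
most-probable explanation (MPE) and node marginals all derive from that
enumeration.  Configuration order is the odometer over variables in schema
order with the last variable fastest; MPE ties resolve to the first
configuration in that order.  Forward ("probabilistic logic") sampling
draws each variable in topological order from its CPT row.

## From annotation panels to inputs

A neuron is excluded when at least ⌈total/2⌉ of its annotators flagged it
uncharacterized (21 of a 42-expert panel); remaining uncharacterized rows
are dropped.  The C4 rule is applied per annotator row: unless a row is
simultaneously translaminar (C1) and displaced (C3), its vertical
orientation is fixed to "no"; a translaminar-displaced row must carry a
directional C4 value.  Per-row application is the only semantics
consistent with building joint label distributions from rows.  Rows with
some of C1–C5 missing outside the uncharacterized mechanism are dropped
with a warning — there is no partial-row semantics.

Two crisp "truths" summarize a panel: the joint truth (modal complete
row) and the marginal truth (per-variable modes).  Mode ties resolve by
canonical category order, making both deterministic.

The C4 rule also acts on distributions: a generating distribution must be
pushed through the rule before being compared with empirical or learned
label distributions (`apply_c4_rule_to_distribution`).  Mass on
non-translaminar-displaced cells moves to their C4 = "no" counterpart;
mass on the unreachable (translaminar, displaced, "no") cells spreads
uniformly over the three directional categories.

## Morphometry

The 18 predictors are computed from SWC reconstructions under two
geometric idealizations: the cortical layer is a horizontal band of the
looked-up thickness centered on the soma (thickness = midpoint of the
species/area interval, e.g. 200–300 µm → 250 µm, so the band reaches
125 µm above and below the soma), and the cortical column is an infinite
vertical cylinder of 300 µm diameter whose axis passes through the soma
centroid.  The soma centroid is the unweighted mean of soma-typed points.

Numerical conventions:

* Segments crossing a shell/band/cylinder/plane boundary are split at the
  exact parametric crossing (quadratic roots for spheres and cylinders,
  linear for planes), which makes the partitions conserve total axon
  length to < 1e-6 µm; accumulated round-off is clamped so X-in never
  exceeds X2.
* Radial shells X3–X5 use 3-D Euclidean distance to the soma centroid; a
  path-distance (arc length along the arbor) option exists but is off by
  default.
* The convex hull X1 uses axon points only, projected along the
  depth-into-slice axis; a degenerate (collinear) hull contributes twice
  its spanned length, a single point 0.
* Centroid distances X12–X14 are measured in the (lateral, vertical)
  image plane.  Points exactly at soma height count as "above"
  (half-open convention, no double counting).  An empty above/below
  subset contributes distance and length 0; the proportions X15/X18 are
  the usual ratios with 0/0 ≡ 0.5.
* Axes are configurable per dataset; by default SWC Y is the pia-directed
  vertical and Z the slice depth.  Soma representations with several
  points (rings/contours) are handled by averaging whatever soma points
  exist.

## The classifier

`LbnConsensusKnn` is organized as a scikit-learn estimator (the method is
fit/predict-shaped, so it composes with sklearn model selection); the
module-level functions are thin wrappers.  Prediction composes:
standardize → k nearest neighbors → closeness weights → sampling budget →
per-neighbor allocation → consensus learning.

* Standardization uses training-fold means and sample (n−1) standard
  deviations.  Zero-variance features are flagged and mapped to zero so
  they drop out of distances.  Per-fold statistics avoid train/test
  leakage; a global mode is available by standardizing before splitting.
* Neighbor distances are Euclidean; ties at the k-th position keep the
  lowest training index.  k must satisfy 2 ≤ k < N (the weight formula
  divides by k−1); k ∈ {3, 5, 7, 9} are the intended operating points,
  default 7.
* Weights w_j = (Σd − d_j)/((k−1)Σd) sum to one and decrease with
  distance; all-zero distances yield uniform weights as the limit.
* The sampling budget is M = k · per_param · c with per_param = 500 and
  c the maximal free-parameter count among the neighbors' LBNs.  Counts
  M_j = w_j·M are integerized by largest-remainder rounding so ΣM_j = M
  exactly.
* Each neighbor's forward-sampling seed is derived from (base seed,
  neighbor id) via a CRC hash, so neighbor order cannot affect the pooled
  counts — and since all scores and MLE depend on the data only through
  counts, the consensus is exactly permutation-invariant.
* The consensus network is learned from the pooled samples with the same
  score/ess settings as LBN learning.

## Evaluation

Jensen–Shannon divergence uses base-2 logarithms, which makes the unit
interval bound tight (disjoint point masses attain 1); it is computed over
the full 320-state enumeration of both networks — exact and cheap.
Global and mean accuracy compare predicted MPEs with joint truths;
per-variable marginal accuracy compares with marginal truths.
Cross-validation is repeated plain (unstratified) k-fold — stratification
is impractical with 320 joint classes — with fold assignment by seeded
permutation chunking, per-repetition derived seeds, and every instance
tested exactly once per repetition.  JS divergences are averaged per
repetition, then summarized as mean ± sd across repetitions (accuracies
likewise).  LBNs are learned once, outside the folds: labels do not depend
on the feature split.

## The synthetic study generator

The generator emulates the study conditions end to end, with defaults
matching the real setting where one exists: 42 annotators per neuron,
m = 18 predictors, 5 class variables; the study default is 5 archetypes ×
200 neurons, annotator ambiguity 0.1 and feature separation 4.

* **Archetypes** are random LBNs: arcs appear with probability 0.3
  (≤ 2 parents per node) and CPT rows are Dirichlet(0.05) draws.  The
  small concentration yields sharply peaked label distributions — matching
  a panel of experts who largely agree on clear cells — and is what makes
  a 42-row panel representative of its generating distribution (median
  empirical-vs-mixture total-variation ≈ 0.16) and the archetype's modal
  label vector stable across panels.
* **Annotation panels** draw each row from
  (1−ambiguity)·p_archetype + ambiguity·uniform, then enforce the C4 rule
  per row (a translaminar-displaced row that drew "no" is reassigned a
  uniformly random directional category).  The uniform contaminant is a
  deliberately simple, analyzable null; confusion-structured noise is a
  config hook.  A configurable fraction of rows is flagged
  uncharacterized.
* **Feature vectors** follow a Gaussian cluster model: archetype
  centroids sit at the vertices of a randomly rotated regular simplex
  whose edge is `feature_separation` in units of the within-cluster
  radial sd (the c-separation convention for Gaussian mixtures, i.e.
  √m × the unit per-feature sd).  The random rotation spreads the
  between-archetype signal across all 18 coordinates so per-feature
  standardization cannot drown it; at separation ≥ 3, same-archetype
  neurons are mutual nearest neighbors after standardization.
* **Morphologies** are branching random walks (4 branches, ~40 steps of
  12 µm) with per-archetype vertical drift, lateral spread and length
  scale, plus a single-point soma and a dendrite stub — the minimum the
  morphometry stage consumes.  The SWC files and metadata exercise the
  extraction path; the cluster-model features drive the classification
  experiments, where the separation knob must be meaningful.

What passing the synthetic recovery experiment shows — and what it does
not: it demonstrates that the pipeline recovers generating label
distributions when morphometric proximity is informative about label
similarity, with realistic panel sizes and annotator noise.  It does not
certify performance on real reconstructions, whose feature clusters are
less separated, whose label distributions are not exactly low-order
factorizable, and whose annotator disagreement is structured rather than
uniform.

## Experiment sizes

The recovery experiment reported by `scripts/acceptance.py` (and asserted
in the test suite) runs one repetition of 10-fold cross-validation on the
200-neuron default study with k = 7 — 200 consensus predictions at
M = k·500·c samples each.  The 20 × 10 plan remains the package default
for real analyses; a single repetition is the package's chosen size for
the routine recovery check, where the fold assignment is the only
quantity the extra repetitions would average over.

## Known limitations

* Only complete categorical data; no evidence-conditioned inference
  beyond full enumeration; no constraint-based structure learning.
* Annotators are treated as exchangeable; no competence weighting.
* SWC is the only reconstruction dialect; Neurolucida ASC must be
  converted externally.
* The exclusion threshold, column diameter, shell radii and axis
  conventions are configurable but default to the values above; results
  are sensitive to the laminar/columnar idealizations by construction.
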