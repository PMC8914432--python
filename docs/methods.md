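# Methods

## Survival model and fitting

The Repairable Conditionally Repairable (RCR) model,
S(d) = e^(−ad) + b·d·e^(−cd), describes single-dose clonogenic survival
with three parameters: `a` (/Gy), the inactivation rate of the directly
surviving compartment; `b` (/Gy), the amplitude of the damaged-but-repaired
compartment; `c` (/Gy), its inactivation rate. S(0) = 1 for any valid
triple, and the model admits closed forms for the mean inactivation dose
(∫₀^∞ S = 1/a + b/c²) and the distal log-slope (→ −min(a, c)).

The fit minimises Σ(ln SF_obs − ln S(d))², the radiobiology convention:
survival spans several decades and log-space residuals equalise relative
error across them. A linear-space objective is available
(`fit(objective="linear")`) for data containing SF = 0; in log mode such
points are excluded with a warning rather than pseudo-counted. Constraints
a, b ≥ 0, c > 0 are enforced by bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF). Because the objective surface is
multimodal, fitting multi-starts from a grid: a₀ from the log-slope of the
two lowest-dose levels, b₀ ∈ {0, 0.5, 1, 2}, c₀ ∈ {0.5, 1, 2, 4}·a₀; the
lowest-RSS optimum wins, ties broken toward smaller b (the simpler,
nearer-exponential curve). Replicate points are fitted jointly, not
averaged, so replicates weight the objective naturally.

On noise-free model-generated data the fit recovers the generating triple
to ≤10⁻⁴ relative error; on Poisson-simulated assays (10⁵ cells per dose,
3 replicates) recovery is within 5%.

## Derived metrics

* **SF2 / SF3.5** — S evaluated at 2 and 3.5 Gy on the fitted curve.
* **D10** — numeric inversion of S at 0.1 by geometric bracketing plus
  Brent's method, to |S − 0.1| < 10⁻¹⁰.
* **D̄ (closed form)** — 1/a + b/c²; rejected for a = 0 (divergent).
* **D̄ (trapezoidal)** — trapezoid rule on a uniform 0.01 Gy grid out to
  the dose where S < 10⁻⁸. The trapezoidal value converges monotonically to
  the closed form as the step shrinks. Note the direction of the
  discretisation bias: trapezoid chords lie above a convex curve, so coarse
  grids *over*-estimate on the convex tail, while the b·d·e^(−cd) term
  makes the curve concave near the origin — no one-sided bound holds for
  general parameters, only convergence. The trapezoidal D̄ integrates the
  fitted curve, not the raw data points: the near-equality of the two D̄
  variants in practice is only explicable that way.
* **D₀** — −1/slope of an OLS fit to ln S sampled on a distal dose window,
  defaulting to the distal 40% of the data's dose range (configurable).
  ln S is evaluated in the log domain (logsumexp), so arbitrarily distal
  windows do not underflow. The asymptote is 1/min(a, c), but when the
  repaired term dominates the local log-slope is −c + 1/d — an O(1/d) bias
  from the b·d factor — so windows must be genuinely distal (d ≫ 100/c)
  before D₀ approaches 1/c within 1%. On data-scale windows D₀ is a
  window-dependent descriptive tail slope, which is how it is used.

## RBE

RBE = reference metric / test metric, per endpoint, per cell line. Summary
rows use the sample (n−1) standard deviation — the printed summary
statistics of the reported five-cell-line RBE table are consistent with n−1, not
n — and CV = SD/mean computed from unrounded values. All rounding is
display-only. With a single cell line the SD and CV are emitted as missing,
not zero.

## Cohort clustering

Average-linkage (UPGMA) agglomerative clustering with Euclidean distance on
the raw univariate SF3.5 values, cut to exactly k clusters
(`scipy.cluster.hierarchy`). Labels derive from ascending cluster-mean
SF3.5 — S, MS, MR, R for k = 4 — not from dendrogram leaf order, so the
ordering is well-defined regardless of tree layout. Entries are sorted by
value (then name) before linkage, making the partition invariant to input
row order; tie-breaking among equal merge heights is scipy's deterministic
order on that canonical input. For 1-D data each cluster is an interval of
the sorted values. SF2 is carried in the panel but not used for clustering.
On the packaged 38-line panel the k = 4 cut isolates three lines (SCC61,
SCC9, HN5) in the resistant cohort with HN31 the most-resistant member of
the MS cohort.

## Gene-signature classification

Per-gene one-way ANOVA F across cohorts (vectorised; p from F(g−1, n−g)),
genes ranked by ascending p with ties broken by descending F then gene id;
zero-variance genes rank last. A moderated variant (`moderated=True`)
shrinks gene-wise pooled variances toward their across-gene mean with a
prior of 4 df — an empirical-Bayes stabilisation for small within-group
df — but the plain F is the default since moderation hyperparameters are a
free choice and the ranking is the tested contract.

Panels of the top-k genes (k from 4 to 500) feed a linear SVM (C = 1;
kernel and C exposed). Validation is repeated stratified 10-fold CV (10
repeats by default), accuracy pooled over folds per repeat and averaged
over repeats; balanced accuracy is reported alongside for imbalanced
designs. `selection_mode="inside_cv"` (default) re-ranks genes within every
training fold — the leakage-free procedure, which keeps label-permuted data
at chance. `"outside_cv"` ranks once on all data, mirroring the simpler
procedure common in the microarray literature; it is measurably optimistic
on null data and is provided for comparison only. When the smallest class
has fewer members than the fold count, stratification is impossible and the
evaluator falls back to plain k-fold with a warning; in that regime a
training fold may hold fewer than two (or zero) samples of a rare class, so
in-fold ranking relaxes its two-per-group precondition and a single-class
training fold predicts its only class.

## TCP and underdosing

Poisson tumor control: TCP = exp(−Σᵢ Nᵢ·S(d)ⁿ) over voxels i. The default
tumor is one voxel, 10⁸ clonogens, radius 0.6203 cm (volume 1.000 cm³),
fully oxygenated, with LET folded into the fitted survival parameters; the
voxel machinery is retained (and partition-invariance tested) so
heterogeneous-dose extensions remain possible, but only uniform dose is
exercised. Fraction number n is continuous: the dose achieving a target TCP
solves n* = ln(−ln TCP / N) / ln S(d) exactly, and iso-effect totals rarely
land on integer fraction counts (a 86.9 GyE prescription at 3 GyE per
fraction is 28.97 fractions). Callers wanting clinical integer schedules
can ceil n*.

Underdosing arithmetic: a GyE prescription at a fixed RBE pins the physical
dose (GyE/RBE_fixed); re-weighting that physical dose by the cell line's
measured RBE gives the biologically delivered GyE, and the difference is
the underdose. All identities hold at full precision internally. Display
formatting follows the conventional dose-table layout: GyE columns rounded
to one decimal, the physical-dose column truncated to one decimal (the
convention under which reported worked rows reproduce exactly). One known
caveat: difference columns computed from already-rounded GyE-actual values
can disagree with full-precision differences by 0.1 GyE; this package
always reports the full-precision difference, rounded once at display.

## Synthetic data

The clonogenic generator draws colony counts from a Poisson law with mean
cells_seeded × PE × S(d) — colony formation is a count process, and no
other noise source is modelled (no inter-replicate dispersion, no counting
error, no plating-efficiency drift). Dose grids default to the photon
(0, 1, 2, 4, 6, 8 Gy) and carbon-ion (0, 0.5, 1, 2, 4, 6 Gy) designs;
cells seeded escalate with dose (100 at 0 Gy up to 10⁴ at 8 Gy) to keep
expected colonies countable; default plating efficiency 0.4 and 3
replicates are conventional assay scales. Consequently, passing tests
demonstrate correct behaviour under Poisson counting noise, not robustness
to the overdispersion or systematic errors of real assays.

The expression generator produces genes × samples Gaussian log-intensities
(baseline 7, noise SD 1 — typical log₂ BeadChip scale) for four cohorts
whose default sizes (8/16/11/3) match the clustered panel. Informative
genes receive a per-gene random permutation (and sign) of the group-shift
vector, so they carry diverse, non-collinear group patterns of the designed
magnitude rather than one shared pattern. Probe-level microarray artefacts
(background, bead summarisation, normalisation) are not emulated, so
classifier results on synthetic data speak to the pipeline's statistical
behaviour, not to any specific gene list.

## Test and acceptance problem sizes

The suite exercises parameter recovery at 10⁵ cells per dose with 3
replicates, classifier calibration with 200–500 genes, 20 label
permutations, and 2–3 CV repeats, and convergence checks on 0.01 Gy grids —
sizes chosen so the full suite runs in seconds while keeping Monte-Carlo
error well inside the asserted tolerances. `scripts/acceptance.py` uses the
same scales, seeded from its `--seed` argument.

## Known limitations

* No LET- or oxygen-dependent survival: RBE is endpoint-ratio only, and
  TCP assumes full oxygenation and fixed beam quality.
* No confidence intervals on fitted RCR parameters.
* No linear-quadratic model; the RCR model is the only survival law.
* The source study's per-cell-line RBE table and TCP curves cannot be reproduced
  absolutely without the underlying raw survival data, which is not
  deposited; the package reproduces the summary arithmetic, the worked
  underdosing rows, the cohort structure, and all pipeline mechanics.
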