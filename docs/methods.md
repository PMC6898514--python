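# Methods

## 1. The estimation problem

Mass cytometry destroys the cells it measures, so an EMT time course yields
independent cross-sectional samples: at each measured time point t we
observe the number of cells n_{t,k} in each of K phenotypic states, hence
occupancy fractions f_t on the probability simplex, but never the
trajectory of any individual cell. Modelling the population as a
time-homogeneous Markov chain within an experimental phase (induction or
withdrawal), the fractions evolve as f_{t+1} = f_t P with P row-stochastic.
The package estimates P per phase from T observed fraction vectors.

**Time scale.** One Markov step is taken per observed interval, even though
the measurement schedule is nonuniform (days 0/2/6/10). A matrix-power
alternative P^(Δt/Δt_min) would respect calendar time but destroys the
convexity of the fitting problem, so it is not offered; fitted transition
probabilities are therefore "per sampling interval", not per day. Fitting a
separate matrix for a single interval is available by calling the fitter on
the corresponding length-2 sub-series.

**The withdrawal phase** starts from the final induction sample: the day-10
TGFβ specimen is the t0 of the MET series (withdrawal day 0), giving 4 + 3
measured samples and 3 fitting intervals per phase.

## 2. The penalized fit

With F = (f_1 … f_{T−1}) and G = (f_2 … f_T),

minimize over row-stochastic P:  ‖G − F P‖²_F + λ Σ_{j≠k} p_jk.

Because P is entrywise nonnegative, the off-diagonal L1 penalty is a linear
term and the problem is a convex QP over a product of K probability
simplices. Self-transitions are unpenalized: remaining in a state is free,
switching is discouraged.

* **Solver.** Accelerated projected gradient (FISTA with adaptive restart,
  numba-compiled; per-row simplex projection by the sort-based algorithm)
  identifies the active set; an exact equality-constrained KKT solve on
  that support, accepted only when primal and dual feasibility hold,
  finishes to machine-level KKT residuals. The unit tests verify agreement
  with an independent scipy SLSQP solve to 1e-6 on random instances.
* **Unidentified rows.** A state never occupied at any predictor time point
  contributes nothing to the data term; its row is set to the identity (the
  penalty-consistent resolution) and flagged.
* **Loss weighting.** The default data term is unweighted squared error on
  fractions. Inverse-multinomial-variance weights (with a half-count
  pseudocount) can be passed explicitly; they re-balance the influence of
  rare states but did not materially improve recovery in our experiments.

## 3. Choosing λ, bootstrap, medoid, hysteresis

* **Cross-validation.** Cells at each time point are partitioned uniformly
  at random into 2 folds; the fit on one fold's fractions is scored by mean
  squared one-step prediction error on the other. The split is repeated
  (default 8 repeats) and the standard error of the CV curve taken across
  the 16 fold errors: with a single 2-fold split the SE is estimated from
  two numbers, and the resulting noise in the one-SE rule intermittently
  selects a λ large enough to delete dominant true transitions. λ_1se is
  the largest λ whose error is within one SE of the minimum (a flat curve
  therefore selects the largest grid value). Default grid: 30 points,
  log-spaced over [1e-4, 1].
* **Debiasing.** `fit_transitions_cv` by default re-estimates magnitudes by
  least squares restricted to the selected support (entries > 0.01),
  removing the L1 shrinkage toward the diagonal; the refit is iterated once
  with re-thresholding. The penalized fit itself is unchanged and available
  via `fit_transition_matrix`.
* **Bootstrap.** Counts at each time point are resampled as
  Multinomial(n = 10,000, observed fractions), independently across time
  points; λ is re-selected per replicate by the same CV (2-fold split),
  and a matrix is fitted per replicate. Box-plot summaries use
  linear-interpolation percentiles, whiskers at the most extreme replicate
  value within 1.5×IQR of the hinges, and an edge's *support frequency* is
  the share of replicates with p_jk > 1e-6.
* **Medoid network.** The replicate minimizing the mean entry-wise L1
  distance to all other replicates; ties break to the lowest index.
* **Hysteresis.** An edge is "supported" in a phase when its bootstrap
  frequency reaches a threshold (default 0.5). The phase comparison reports
  edges supported in exactly one phase, per-phase supported-edge counts,
  and bidirectional pairs (j→k under induction with k→j under withdrawal).

## 4. Identifiability of aggregate transition inference

This is the load-bearing caveat of the whole approach. Aggregate fractions
constrain only the **net** flow of occupancy: any circulation component
(flux balanced in and out of a state within an interval) is invisible. Two
consequences, both verified numerically during development:

1. **Serial chains are unrecoverable.** For a chain E1→E2→…→M near
   quasi-stationary throughput, the minimum-switching explanation of the
   marginals moves only the net changes directly from sources to sinks,
   with far less off-diagonal mass than the truth. No choice of λ fixes
   this: the truth is simply not the optimum of any member of the penalized
   family.
2. **Support selection is the fragile step even in favourable regimes.**
   With 3 intervals the per-column source profiles live in R³; a source can
   be faked by a nonnegative mixture of other states' occupancy profiles
   whenever the profiles' curvature (Jensen) gaps are below the multinomial
   noise (≈ 0.004 at n = 10,000). Given the correct support, magnitudes are
   well determined (restricted least squares achieves ≈ 0.015 max-entry
   error in the default scenario).

The identifiable regime therefore requires dynamics where each occupied
state is (approximately) a pure source or pure sink on the sampling time
scale, with draining states having well-separated decay constants. Real
EMT data may or may not satisfy this; bootstrap support frequencies remain
meaningful far outside the regime where individual magnitudes do, and the
hysteresis comparison only requires support detection.

## 5. The synthetic cohort

The default scenario emulates an 8-state TGFβ induction/withdrawal
experiment: states E1–E3 (epithelial), pEMT1–3 (partial), M (mesenchymal),
MET (withdrawal-specific hybrid); 10,000 cells per time point at induction
days 0/2/6/10 and withdrawal days 2/6/10 (the day-10 induction sample is
the withdrawal t0, so the two series share that sample).

* **Dynamics.** During induction, E1 drains fast (self-transition 0.45)
  into pEMT1/pEMT2 and E3 more slowly (0.75) into pEMT3; E2 and all deeper
  pools persist. During withdrawal, pEMT3 relaxes back to E3 (self 0.60)
  and M exits through the MET state (self 0.38, M→MET = 0.62), which has
  zero inbound probability during induction — the hysteresis edge. The
  drain→sink structure with separated rates places the ground truth inside
  the identifiable regime of §4; persisting pEMT pools match the observed
  persistence of hybrid states after TGFβ withdrawal. These defaults were
  fixed from the identifiability analysis, not tuned to any test outcome.
* **Marker model.** Within a state, the six clustering markers are Gaussian
  on the arcsinh scale (SD 0.4) with means encoding the expected
  phenotypes: epithelial states high in E-Cadherin/CD24/MUC1, partial
  states co-expressing epithelial and mesenchymal markers, M high in
  Vimentin/CD44/Twist, and MET a distinct epithelial-leaning hybrid. The
  per-state generative law is a modelling choice — the data source reports
  only state phenotypes, not distributions.
* **What a green test does not establish.** The simulator draws i.i.d.
  cells per time point (cross-sectional, like the assay) with exactly
  Markovian state dynamics, no proliferation/death differences between
  states, no batch effects, and Gaussian marker noise. Passing tests
  demonstrate correctness of the machinery under the model's own
  assumptions, not robustness to their violation; in particular
  state-dependent growth rates would bias all transition estimates.

**Known red check.** The structural-recovery check in the acceptance suite
(median max-entry error ≤ 0.05 and support F1 ≥ 0.9 over 20 cohorts) fails
by design of the problem, not of the code: across 20 seeds the CV-selected,
debiased fits reach median max-entry error ≈ 0.06–0.13 and pooled support
F1 ≈ 0.75–0.8, and even an oracle λ (chosen against the truth) cannot meet
the stated thresholds at T = 4 per phase, K = 8, n = 10,000 (21 independent
equations vs 56 free parameters; §4). The thresholds are retained as the
statement of what full structural recovery would require.

## 6. Reference map and projector

* **Embedding.** t-SNE (perplexity 30, PCA initialization, fixed seed) on
  the six clustering markers; coordinates are centered. The embedder is
  pluggable (`method="pca"` offers a fast deterministic alternative) since
  stochastic-neighbor embeddings are not reproducible across
  implementations; determinism is guaranteed only for a fixed seed, input
  order and library version.
* **Centers.** Per state, cells are restricted to the state's peak time
  point (argmax of its fraction over time). The plane is gridded at
  candidate square bin sides 1–8 map units (native embedding units — the
  only intrinsic scale); the side with the largest absolute change in
  densest-bin occupancy between adjacent sizes is chosen (larger side of
  the pair, ties to the smaller), and the center is the centroid of the
  densest bin's cells.
* **Segmentation.** Voronoi cells of the centers are built as intersections
  of half-planes and clipped to an alpha-shape boundary (Delaunay triangles
  with circumradius ≤ 1/α, unioned). α defaults to the largest circumradius
  quantile giving a connected, hole-free shape containing ≥ 99% of points,
  and falls back to the convex hull with a warning. A true annulus has a
  hole and is thus outside the simple-polygon contract; its exterior is
  essentially the hull.
* **Projector.** 6 → 11 → 2 network, logistic hidden units, linear output,
  L-BFGS with weight decay 1e-4, trained on a 90% split (stratified by
  state when labels are given) after min–max scaling by training-split
  ranges. The stored ranges are applied verbatim at projection time with
  out-of-range values clipped — never rescaled — so a shifted sample
  saturates visibly rather than silently renormalizing. Stability is
  reported as the SD across 10 fold-models' predictions on the common
  holdout. Hidden-size selection (the holdout sweep) is available but the
  default of 11 units is fixed.
* **Classification.** k = 1 nearest-center by default (identical to
  Voronoi membership for interior points; the k for the classification is
  not specified by the source, and 1 is the least-assumption choice); ties
  go to the lower state id; out-of-boundary cells are assigned but flagged.

## 7. Preprocessing defaults

* arcsinh cofactor 5 (the CyTOF field standard). The alternative published
  value 552 is accepted via the `cofactor` argument; it is flagged as a
  suspected misprint and therefore not the default.
* Viability/apoptosis thresholds are user-supplied per channel (gates are
  dataset-specific); a cell is removed if cisplatin exceeds its threshold
  or either cleavage channel does.
* Density-dependent downsampling: local density = neighbor count within a
  radius (default 5× median nearest-neighbor distance); keep probability
  min(1, c/density) with c calibrated by bisection to the target size.
* Rare-state pruning: states under 1% prevalence (inclusive boundary:
  exactly 1% survives) are dropped, their cells marked unassigned, and
  survivors renumbered preserving order.
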