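# Methods

## Detection data from interviews

Each key-informant interview about a focal 5 × 5 km grid cell is treated as
one survey replicate. The identification flowchart yields a per-species
state: **2 (certain)** — every look-alike photo (tiger for leopard, jackal
for wolf) and the focal species identified without a hint, and a reported
sighting inside the focal grid within the past year; **1 (uncertain)** — a
hint was needed or a look-alike was misidentified, sighting still valid;
**0 (non-detection)** — identification fine but no valid sighting (none
reported, on/outside the border, or older than a year); **FAILED** — the
focal species was not identified even with a hint, voiding the replicate
for that species only. Species without look-alike pairs (hyena, sloth
bear, blackbuck) have an empty, vacuously-correct paired set, so their
certainty rests on the hint and sighting validity alone.

Replicate validity follows subgrid coverage: three or four of the four
subgrids make an independent replicate; exactly two requires merging with a
complementary respondent (union ≥ 3 subgrids). A merged replicate keeps
the union of subgrids, the longer herding experience, and per species the
combined outcome in which FAILED dominates and otherwise the higher state
wins — one failing respondent invalidates the pair for that species, which
is the conservative reading of the combined-entry protocol. Experience
reported as a range enters as its midpoint. Border sightings are coded 0
with no neighboring-cell credit.

The binary layer keeps only certain detections (1 iff state 2): uncertain
records are discarded rather than modelled, because the three-state model
is poorly identified in this data regime (below). Sites whose replicates
are all FAILED for a species are dropped from that species' matrix, which
is why per-species site counts differ.

## Likelihoods and fitting

The single-season likelihood marginalizes the latent occupancy state per
site; missing replicates contribute a factor of 1 (skipped, never
imputed), accommodating 1–7 interviews per site. Both Ψ and p use a logit
link on standardized covariates. Site covariates are z-scored (sample SD,
ddof = 1) over the **entire district grid** — sampled and unsampled cells —
so fitted coefficients project to unsampled cells on the same scale.
Replicate-level experience is z-scored over the interviews entering the
matrix; the binary whole-grid-covered indicator stays on its 0/1 scale
(standardizing a binary indicator only rescales its coefficient).

Fitting is quasi-Newton (BFGS) with the analytic gradient, from ten
jittered starts around the origin by default. Standard errors come from
the inverse observed information (Hessian by central differences of the
analytic gradient). A fit is **converged** when the gradient max-norm is
below 1e-4 and the Hessian is positive definite; anything else is flagged,
never raised, and excluded from model ladders. The 1e-4 norm reflects the
scale at which BFGS reliably terminates on these likelihoods; estimates are
insensitive to tightening it. Quasi-separation is a real phenomenon here:
when every detected site lies above some threshold of a covariate, the
likelihood is maximized by a step function and the slope diverges — such
fits fail the Hessian test and drop out of the ladder, mirroring how
non-converging models are discarded in this workflow.

The false-positive variant models the three states directly: occupied
sites emit state 2 with probability p₁₁·b, state 1 with p₁₁·(1−b), state 0
otherwise; unoccupied sites emit state 1 with probability p₁₀ and can never
emit state 2 (certain detections are error-free by construction). p₁₀ and
b are intercept-only. A site with a certain detection forced toward the
unoccupied branch hits a clipped-likelihood guard rather than −∞. The fit
reports boundary flags (estimates within 1e-3 of 0/1 on the probability
scale, or no uncertain records at all — the structurally non-identifiable
case), the Hessian condition number, and a flat-profile flag (non-PD or
ill-conditioned Hessian, or logit-scale SE above 10). Under the realistic
sparse-uncertainty regime these diagnostics fire in the majority of
simulated surveys, which is the documented rationale for the binary
collapse being the production path.

## Selection and averaging

Selection is two-step: detection structure first with Ψ at its null, then
occupancy structure with the best detection model fixed. Each step fits
the global additive model, drops covariates with SE ≥ |β| (a non-converged
global skips the simplification with a warning), estimates overdispersion
on the simplified global, enumerates the null plus all additive
combinations of the survivors (collinear pairs, |r| ≥ 0.6 inclusive, never
co-occur; the global model resolves such pairs by a configurable priority
list, defaulting to menu order), and ranks by QAICc.

ĉ is a MacKenzie–Bailey parametric bootstrap: the Pearson χ² of observed
versus expected detection-history counts — sites cohorted by missingness
pattern, all 2^k histories enumerated per cohort — divided by the mean of
the same statistic over B parametric-bootstrap refits, floored at 1
(underdispersion is not credited). Default B = 1000; at least 100 is
recommended for stable means (smaller B warns, B < 1 errors). Bootstrap
refits start at the MLE with 2 starts. If no model suitable for the GOF
step converges, ĉ falls back to 1 with a warning. Note the single
observed-χ²/bootstrap-mean ratio is noisy; only its expectation is 1 under
a well-specified model.

QAICc uses quasi-log-likelihood logL/ĉ, K = number of estimated parameters
**plus one** (the variance-inflation slot), and n = number of sites; these
conventions reproduce published quasi-likelihood ladders of this design
exactly. Akaike weights are computed over the full converged ladder;
models within ΔQAICc ≤ 2 (inclusive) are retained and their weights
renormalized for averaging. Per-grid averaged SE uses the unconditional
(within + between model) variance. Cells with more than ¾ waterbody cover
are excluded from the surface. The district summary is the spatial mean of
per-grid averaged Ψ; its headline SE is the delta-method SE of that mean
(grids fixed) combined across models, and the mean of per-grid SEs is also
reported since either reading of a published "district SE" is defensible.

## Synthetic data

The generator mirrors the study design at its defaults: a 230-cell
district with 119 sampled cells, 1–6 interviews per cell, Ψ ≈ 0.5 at the
covariate mean and per-replicate detection ≈ 0.3, certainty
P(state 2 | true detection) = 0.85, per-replicate false-positive rate 0.02
(always recorded as uncertain, never certain), failed-identification rate
0.03, and 10% of replicates emitted as complementary two-subgrid interview
pairs that the ingestion stage must merge. Covariate fields are linear
maps of a latent Gaussian with configurable cross-correlation (infeasible
targets are rejected as non-PD), areas clipped to the 25 km² cell; a few
percent of cells are waterbody-dominated to exercise the exclusion rule.
Respondent experience is generated on a latent standard-normal scale and
written out in raw years; re-standardization at ingestion reproduces the
generating scale up to sampling error. Same seed, same bytes: all
randomness flows from numpy's PCG64 seeded via `SimConfig.seed`.

What the generator does **not** emulate: spatial autocorrelation in
occupancy (the likelihood assumes site independence), respondent-specific
reporting biases beyond the certainty split, movement of pastoralists
beyond the subgrid-coverage flags, and real land-cover geometry. Passing
recovery tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to their violation.

## Numerical and design choices

- Livestock biomass: head counts × configurable mean body masses (defaults
  cow 250, buffalo 350, sheep 30, goat 25 kg), apportioned to grids by the
  village's area share; apportionment conserves totals exactly.
- Open-natural-ecosystem area counts raster pixels with membership
  probability strictly greater than 0.5.
- Report tables round half-up to 2 decimals. Two published naive
  occupancies (10/118, 45/119) appear rounded up in the source; the
  package reports the standard half-up values (0.08, 0.38) and documents
  the discrepancy rather than reverse-engineering it.
- Reconstructing published ladder numbers from printed inputs inherits the
  tables' 2-dp rounding: QAICc agrees to ±0.015 (±0.01 for most rows) and
  weights to half a printed unit.
- Ties at ΔQAICc exactly 2.0 are retained (inclusive rule).
- Coefficient summary tables report each covariate from the top-ranked
  model in which it first appears.
- Problem sizes in the test-suite experiments (e.g. 200 recovery
  replications at 500 sites × 5 replicates; 100 selection trials at 300
  sites; bootstrap B of 25–100 in desk-scale runs) were chosen as the
  smallest sizes at which the Monte-Carlo error is comfortably below the
  tolerances being asserted.

## Known limitations

- No multi-season dynamics, spatial random effects, abundance-mediated
  detection or Bayesian fitting.
- The false-positive model is a diagnostic, not a production estimator;
  its covariate support is limited to Ψ and p₁₁.
- The correlation screen is pairwise; higher-order collinearity is not
  detected.
- District-wide prediction extrapolates to unsampled cells on the shared
  standardization scale; out-of-range covariate values warn but are not
  truncated.
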