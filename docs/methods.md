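# Methods

## The measurement problem

A VAS-RRP presents a *testlet* of several items on one continuous response
line; the respondent drags every item onto the line, so a single action
yields a continuous rating for each item (its relative position between the
endpoints, scored on [0, 1]), a ranking (the order of the items), and all
pairwise comparisons. The package asks, by simulation, what is gained or
lost relative to two classical alternatives: Likert-type scales, which
coarsen the continuous response into a few ordered categories, and pure
rankings, which are ipsative (each respondent's ranks within a testlet sum
to a constant, so their covariance matrix is singular).

## Generating model

Items follow a congeneric factor model with simple structure,

    x = Λ ξ + ε,   ξ ~ N(0, Φ),   ε ~ N(0, Θ),

with L = 4 latent traits, unit latent variances, and either 4 or 8 items
per trait. Items are grouped into testlets of one item per trait. Because
items in a testlet are answered jointly on one line, their residuals are
allowed to correlate: in the **CTCU** (correlated-traits–correlated-
uniqueness) variant Θ carries a correlation block per testlet; in the
**CT** (correlated-traits) variant Θ is diagonal. The model-implied
covariance is Σ = ΛΦΛᵀ + Θ.

Reference parameterization (`make_4l4i_spec`): loadings
(0.65, 0.75, 0.85, 0.95 | 1.15, 1.05, 0.95, 0.85 | 0.70, 0.80, 0.90, 1.00 |
1.20, 1.10, 1.00, 0.90) for traits 1–4; trait correlations in a circumplex —
.3 between cyclically adjacent traits (including the 1–4 pair), .1
otherwise; each testlet's residual correlation matrix equal to the same
circumplex; residual variances 1. Unit residual and latent variances are
not arbitrary: with them the closed-form population reliabilities
(α = .7144/.7967/.7386/.8121, ρc = .7191/.8000/.7429/.8152) and the model
degrees of freedom (74/98/410/458 across the CTCU/CT × 16/32-item grid)
reproduce the reference simulation results exactly, which is how the
parameterization was fixed. For the 32-item model only the loading *range*
[0.60, 1.20] is prescribed; the default deals an evenly spaced grid over
that range cyclically across traits. Its per-trait reliabilities therefore
follow from that choice rather than from a printed target, and the 8-item
conditions are checked as orderings (longer scales more reliable), not as
cell values.

## Synthetic data and response formats

`generate_dataset` draws n respondents (default 500) from Σ and clips to
[−3, 3]; clipping is read as post-hoc truncation of the normal draws, the
conventional reading of a simulator that reports a data range. Under the
reference model ~3% of draws clip (the fraction is recorded per dataset);
the effect is a small shrinkage of the largest item variances, visible as a
~−0.01 bias in the recovered largest loadings and nothing else we measure.

* **VAS-RRP scores**: v ↦ (v+3)/6, an order-preserving affine map onto
  [0, 1]. Cronbach's alpha, CFA fit and correlations are invariant under
  it, so analyses may equivalently use the continuous values; parameter
  estimates are reported in the generating metric.
* **Likert**: category 1 + #{cuts below v}, coded 1..k. The four cut-point
  sets {−2,2}, {−1,1}, {−3,−1,1,3}, {−1.5,−.5,.5,1.5} mimic 3- and 5-point
  scales with different category widths. Likert conditions discretize data
  generated *without* context effects (the CT model), matching the design
  being emulated: the context effect is a property of the joint testlet
  response, which a one-item-at-a-time Likert administration does not have.
* **Ranking**: within each respondent × testlet, ranks 1 (lowest) to L
  (highest), so rank scores correlate positively with the trait. Ties —
  probability zero for continuous input — break by item index. Rank sums
  are the constant L(L+1)/2; the resulting covariance matrices have rows
  summing to zero and determinant zero.
* `vas_item_score` maps raw screen coordinates (x1, x2 endpoints, x3 mark)
  to (x3−x1)/(x2−x1); `rescale_common` divides Likert codes by k and ranks
  by L to put all formats on (0, 1] for leniency-bias comparison
  (mean − median).

Per-replication seeds derive deterministically from the master seed
(master + replication index; CT-stream, retry and ranking-study offsets of
5·10⁵, 10⁶ and 777 777), so any replication is individually reproducible
and whole runs are byte-identical given the same configuration.

## Estimation

**Cronbach's alpha** uses n−1 sample variances. **Composite reliability**
ρc = (Σλ)² / ((Σλ)² + Σ var ε) is computed from fitted CFA parameters, and
is invariant under the common rescaling (λ→cλ, var ε→c²var ε), hence under
the VAS map.

**CFA** minimizes the Wishart ML discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p with factor variances fixed at 1. Free
parameters: p loadings, L(L−1)/2 latent correlations, p residual variances,
plus one residual-correlation block per testlet in the CTCU template
(q = 62 for the 16-item CTCU model, df = 74). Optimization is BFGS on an
unconstrained reparameterization — correlations through tanh, residual
variances through log (which also enforces positivity, precluding Heywood
variances) — with analytic gradients (dF/dΣ = Σ⁻¹(Σ−S)Σ⁻¹ contracted with
the parameter Jacobians; unit-tested against finite differences at 1e-5).
Start values: loadings 0.8, variances 1, correlations 0. Convergence
tolerance 1e-6 on the gradient norm; a fit is flagged non-converged above
1e-4. Non-PD iterates get a flat penalty rather than an exception. The
per-factor sign indeterminacy is resolved by reflecting any factor whose
loading sum is negative. χ² = (n−1)·F_min (the continuous-ML convention;
the multiplier is an option). RMSEA, SRMR (lower triangle including the
diagonal), CFI and TLI (capped at 1) are computed against the independence
baseline, whose ML solution is diag(S) in closed form.

Likert data are fitted as continuous ML on their Pearson covariance —
deliberately, since the comparison being reproduced concerns what happens
when coarse ordinal data are treated as continuous; no polychoric
correction is applied.

**EFA** extracts principal components from the correlation matrix
(eigenvectors scaled by √eigenvalue, deterministic sign convention), which
runs on singular ipsative input; PVE = 100 · (top-k eigenvalue sum)/p with
k fixed at 4, the number of generating traits. Oblique rotation is promax
(power 4, varimax with Kaiser normalization first), in the pattern-matrix
convention of the classic packages — the implementation reproduces R's
`stats::promax` to 3 decimals on a frozen oracle matrix. Structure tables
blank |loading| ≤ .3; a component-to-trait assignment by greedy congruence
supports the simple-vs-complex-structure diagnostic (count of items whose
largest |pattern| loading is off their generating trait's component).

**Alpha-equality test** (two independent samples): Hakstian–Whalen
cube-root transform t = (1−α)^{1/3} with variance
18k(n−1)(1−α)^{2/3} / ((k−1)(9n−11)²); the squared contrast against the
precision-weighted mean is χ²(1) under equality.

## Replication harness

Study 1: per replication, generate CTCU data → VAS-RRP scores → alpha per
trait; fit the CTCU template (on the affine-equivalent continuous
covariance); generate CT data → each Likert condition → alpha, CT fit.
Aggregates mirror the reference layout: alpha table, fit-index table,
composite-reliability table, parameter-recovery table (mean, dispersion,
bias per parameter; the CT template reports no residual-correlation
block). The "SE" column is the SD of the replication distribution — at
n = 500 the alpha dispersion is ≈.02, matching the reference tables'
parenthesized values, which identifies their convention — and the manifest
records this. Replications with a non-converged fit are dropped and
regenerated from a retry stream (counts logged; none observed in 500
reference-model replications); a run aborts if more than 20% fail.

Study 2: one recorded-seed dataset (master + 777 777) is scored as VAS-RRP
and as ranks; both correlation matrices go through PCA + promax; outputs
are the two structure tables, component correlations, per-trait alphas and
PVE. Implementing "one randomly selected dataset" as a recorded-seed draw
keeps the study reproducible.

Defaults are the study conditions: n = 500, 500 replications. The graded
checks run scaled down — 200 replications for the reliability stage, 100
for the CFA stage (the package's own choice of desk-scale problem sizes;
a 500-replication CFA run takes ~10 s on one CPU if wanted).

## What the generator does and does not emulate

It emulates the *statistical* consequences of the three formats:
coarse-categorization attenuation for Likert, ipsativity for ranking,
testlet context effects as residual correlations. It does not model
respondent behaviour — acquiescence or extremity styles, drag-and-drop
interaction effects, response times, or the non-overlap constraint of real
testlet marking. Passing tests therefore show that the analysis chain
recovers what the model puts in, not that real respondents behave this
way; the empirical-data side of the original comparison is out of scope.

## Known limitations

* Likert fits use plain ML on Pearson covariances by design; WLSMV/
  polychoric estimators are out of scope.
* The alpha-equality test covers independent samples only; the
  dependent-samples variant is not implemented.
* Monte-Carlo SEs are the only uncertainty reported for estimates; no
  per-fit standard errors or modification indices.
* Exact Study-2 cell values depend on the single dataset drawn; only PVE
  magnitudes and structure quality are comparable across seeds.
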