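# Methods

## Model

Each feature (probe-set or gene), in each individual of a matched
case-control pair, is modelled as a zero-mean Gaussian process over time
(weeks since birth) with a squared-exponential kernel and additive iid
Gaussian noise:

    x(t) = f(t) + ε,  f ~ GP(0, k_se),  k_se(t,t') = σ²_se exp(−(t−t')²/(2ℓ²)),  ε ~ N(0, σ²_ε).

Before every fit the series is mean-centred; the case, control and
pooled (case + control) series are centred **independently**, each by its
own mean. A consequence worth stating explicitly: a constant offset
between case and control survives inside the pooled series (only the
pooled mean is removed), so the joint model must explain it and the
Bayes factor *detects* constant level shifts as well as shape
differences. Shifting both groups by the same constant changes nothing.
For window predictions the centring means are added back, so the
compared Gaussians live on the original intensity scale.

## Hyperpriors

| parameter | prior | default | rationale |
|---|---|---|---|
| ℓ (weeks) | Gaussian(μ=30, σ²=6) | — | months-scale dynamics; short length-scales improbable |
| σ_se | half-Student-t(ν=20, scale=1) | — | weakly-informative on the signal *standard deviation* |
| σ²_ε | scaled-inv-χ²(ν=1, τ²=0.01) | — | keeps the noise floor small, heavy right tail |

All three are configurable (`HyperPriors`). Two readings the notation
admits were pinned as: the noise prior's 0.01 is the **scale** parameter
τ² of the scaled-inverse-χ² (equivalently InvGamma(ν/2, ντ²/2)); the
"square-root Student-t" is a half-t on the signal **standard deviation**.
The same priors are used for case, control and joint fits.

## Marginal likelihood via central composite design

Type-II maximisation of the marginal likelihood overfits the 3–12-point
series this method targets, so p(X|M) = ∫ p(X|M,θ) p(θ|M) dθ is instead
approximated by a weighted sum over R deterministic design points,

    p(X|M) ≈ Σ_r p(X|M,θ_r) p(θ_r|M) Δ_r ,

evaluated in log space with log-sum-exp. Construction, on the natural-log
scale of θ = (ℓ, σ²_se, σ²_ε) (priors pick up the change-of-variables
Jacobian):

1. **Mode**: multi-start L-BFGS-B on the log joint with analytic
   likelihood gradients and closed-form prior gradients; 5 restarts
   sampled N(0, 0.5²) around the prior means, seed 0, bounds ±12 on each
   log-parameter. The negative Hessian at the mode comes from a
   central-difference stencil (step 1e-4), projected to the PD cone by
   eigenvalue clipping if needed (logged).
2. **Design**: in the whitened space of the Hessian, the mode, 2d star
   points and the full 2^d factorial (d = 3 ⇒ R = 15; coincident points
   are merged when d < 3), all at radius r₀ = f√d with f = 1.1.
3. **Split-Gaussian scales**: along each whitened half-axis, bisection
   finds the distance at which the log joint has dropped r₀²/2 below the
   mode; design points are stretched per-axis by these scales, so every
   non-mode point carries q(θ_r|M) = exp(−r₀²/2) exactly.
4. **Weights**: in standardised coordinates the non-mode points share one
   weight chosen so the rule integrates a standard Gaussian and its
   second moment exactly; the mode takes the complement, which is
   positive for any f > 1 (mode mass = 1 − 1/f²). Weights map to
   log-hyperparameter volumes through the whitening determinant and the
   local split scales (the mode uses the per-axis average).

Measured accuracy: against fine-grid quadrature the estimate is within
~0.1 nats on 1-free-hyperparameter problems and −0.08 ± 0.06 nats
against 3-d brute-force quadrature on 8-point series.

The CCD **predictive** for a time grid T\* mixes the per-point exact GP
posteriors with weights q(θ_r|M)Δ_r renormalised to sum to one. The
mixture covariance is the weighted average of the per-point covariances
as the estimator is defined — the between-component mean-dispersion term
of the law of total variance is deliberately omitted; predictive
variances are therefore mildly understated when hyperparameters are
uncertain.

## DE scores

**BF-score** (time course): log p(x_A|M_A) + log p(x_B|M_B) −
log p(x_S|M_S) with each term CCD-estimated on the independently centred
series. Threshold 4 (strict inequality; ≈ 54.598 linear). The score is
invariant to negating both groups and to common offsets; it is
*direction-agnostic* — opposite regulation in different pairs scores as
highly as consistent regulation.

**KL-score** (window): the case and control predictives on a weekly grid
of 26 points ending at (and including) the event week are stacked into a
52-dimensional block-diagonal Gaussian M₀ (zero cross-covariance between
case and control blocks); the joint predictive is duplicated into M₁
with the same block structure. The score is the symmetric KL divergence
½KL(M₀‖M₁) + ½KL(M₁‖M₀), computed via Cholesky log-determinants with
the same jitter ladder as the GP fits. GPs are fit to the **full**
series, so windows without observations are handled by interpolation /
extrapolation; variances then revert toward the prior. The dimension is
2 × 26 for the default window; window length and resolution are
configurable, and the grid is anchored to end at the event week.

**Threshold calibration**: KL-scores have no Bayes-factor-like scale, so
the window threshold is set to the mode of the KL-scores of features
(pooled over all pairs) whose BF-score lies within ±1 of the BF
threshold. "Mode" of a continuous sample needs a density estimate: a
Gaussian KDE with Silverman bandwidth on log(1+score), argmax on a
512-point grid, mapped back. Fewer than 30 borderline features triggers
a logged fallback to the default threshold 250. The pathway-level
permutation test self-normalises against liberal or stringent
thresholds, so the exact value is not critical.

**Probe-set collapsing**: one score per gene per pair = the maximum over
that gene's probe-sets, chosen independently per pair.

Pairs with one group entirely unobserved are skipped and reported.
Scoring is feature-wise independent; results are identical for any
worker count (`n_jobs`).

## Pathway enrichment

Scaled overlap f_ij = |pathway_i ∩ DEG_j| / |DEG_j| + α (α = 10⁻⁶
keeps the geometric mean finite at zero overlap); the pathway statistic
is the geometric mean of f_ij over pairs, computed in log space. A pair
with zero DE genes is a configuration error at the API level (drop the
pair); the pipeline drops such pairs from the enrichment automatically
with a warning.

The null distribution permutes the **feature labels** of the G × m score
matrix — one shared permutation per iteration, moving whole rows, which
preserves the correlation of a feature's scores across pairs. After each
relabelling, probe-sets are re-assigned to genes, re-collapsed (max) and
re-thresholded, and every pathway's statistic recomputed; this loop is
vectorised (boolean DE matrix, bincount scatter per pair, one matrix
product for all pathway overlaps). Empirical p = (r+1)/(B+1) — the
add-one form guarantees validity and p > 0; the observed labelling is by
construction counted through the ≥ comparison. An exhaustive mode
enumerates all G! labelings for tiny problems and is tested against an
independent brute-force enumeration. Default B = 100,000; the
calibration and recovery checks here use B = 2,000. Pathway membership
is intersected with the platform universe (genes present after mapping)
up front; pathways with no platform genes are reported with p = 1 and
flagged, never dropped silently. BH correction via statsmodels; results
are annotated at FDR < 0.1 and FDR < 0.05 by default.

## Combined baseline

All cases pooled into one series, all controls into another; the same
scoring machinery (same centring, thresholds, collapsing) runs once per
feature on this single pseudo-pair. Enrichment of the single DE list
uses a one-sided hypergeometric (Fisher's exact) upper tail on the
platform universe, BH-corrected. The window variant reuses the
personalised KL threshold (configurable) and takes the median event time
across pairs as the pooled event anchor.

## Synthetic data

The generator emulates the target study design: m pairs (default 6),
each individual sampled 3–12 times (sorted uniform draws — irregular
spacing, case and control at non-identical times) over a 104-week
horizon, 1–3 probe-sets per gene, log-intensity baselines ~ N(7, 1).

* **Null features**: case and control of a pair observe one latent GP
  draw (sampled jointly at both groups' times) with independent noise.
* **DE features**: a gene is active per pair with probability 0.25
  (background) — pairwise DEG-overlap in the observed-data regime the
  method targets (~14%) — through one randomly chosen carrier probe-set;
  the perturbation is an independent draw (default), an additive
  Gaussian bump confined to the pre-event window (sign flips between
  pairs with probability 0.5), or a sign flip of the shared draw.
* **Planted pathways**: member genes drawn disjointly from the gene
  pool, active per pair at their own rate (default 0.4).
* Trajectory draws use ℓ = 30 wk, σ²_se = 1, σ_ε = 0.5 (signal-to-noise
  σ²_se/σ²_ε = 4).

Identical (config, seed) reproduces byte-identical files. What the
generator does **not** emulate: probe-level microarray artefacts, batch
effects, normalisation residue, heavy-tailed noise, and gene-gene
correlation outside planted pathways. Passing tests therefore certify
the inferential machinery under the model's own assumptions, not
robustness to real microarray pathologies.

## Numerical choices

* Jitter ladder: start 10⁻⁸ × mean diagonal, ×10 per step, cap 10⁻²;
  exceeding the cap raises a linear-algebra error carrying the
  feature/pair context.
* Strict inequalities at both DE thresholds (score exactly at threshold
  is not DE).
* Ties in the permutation test are counted as exceedances (≥), which is
  conservative.
* All stochastic components (restart initialisation, permutations,
  simulation) consume explicit seeds; pipeline outputs embed a config
  hash, and a rerun with the same config + seed is byte-identical.

## Problem sizes used in the checks

The acceptance script and test suite exercise: 3-point series for the
quadrature oracle; 4-dimensional Gaussians at 10⁶ Monte-Carlo draws for
the KL oracle; a 5-feature × 2-pair matrix fully enumerated (120
permutations); 300 features × 6 pairs × 500 pathways at B = 2,000 for
null calibration; and a 6-pair, 200-gene dataset at 8 samples per
individual for planted-pathway recovery and ROC discrimination. These
sizes keep a full run in minutes on one CPU while leaving each check
statistically meaningful.

## Known limitations

* Gaussian observation model only; no sparse approximations (series are
  short by design); squared-exponential kernel only.
* The predictive covariance omits the mean-dispersion term (see above).
* BF-score discrimination degrades on very short series: marginalising
  hyperparameters lets the joint model absorb case-control divergence
  into its noise variance, compressing large scores. At the default
  synthetic regime (8 samples/individual, 104-week horizon, ℓ = 30) the
  measured ROC AUC against planted truth is ≈ 0.89, a few points below a
  clamped-true-hyperparameter oracle (≈ 0.93) — the cost of honest
  hyperparameter uncertainty at n = 8.
* The combined baseline inherits the homogeneity assumption it is meant
  to illustrate; opposite-direction perturbations cancel in it by
  design.
* Non-matched designs and multi-window scans are out of scope.
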