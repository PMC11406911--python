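# Methods

## Model

Counts are taxa-by-samples, `y_ij` for taxon *i* in sample *j*. Each taxon is
modelled as zero-inflated negative binomial (ZINB): with probability `pi_i` the
observation is a structural zero (the taxon is absent from that sample's
community); otherwise it is a draw from `NB(mu_ij, theta_ij)` in the
mean/dispersion parameterization, where `Var = mu + mu^2/theta` and
`theta -> inf` recovers the Poisson. Sequencing depth enters both NB
parameters through log-linear links:

```
log mu_ij    = beta0_i + beta1_i * x_j    (+ beta2_i * g_j in two-group designs)
log theta_ij = kappa0_i + kappa1_i * x_j
logit pi_i   = gamma_i
```

`x_j` is the natural log of the library size of sample *j* (the column sum of
the unfiltered count matrix; taxon filtering never redefines depth). Natural
log is used throughout; a different base only rescales the slopes. `beta1_i`
is the taxon's *sequencing efficiency*: how strongly its observed abundance
responds to depth. Scaling normalizations (TSS, TMM, CSS, ...) implicitly
assume `beta1_i = 1` and `kappa1_i = 0` for every taxon; this package exists
because neither holds in real data. The zero-mass probability is
intercept-only (taxon-specific, constant across samples): richer `pi` models
fit worse in practice and are harder to identify.

## Estimation

Each taxon is fit independently by maximum likelihood via EM, treating the
structural-zero membership as latent:

* **E step** — the posterior weight that an observed zero is structural:
  `w_j = pi / (pi + (1 - pi) f_nb(0; mu_j, theta_j))`, and `w_j = 0` for
  `y_j > 0`; computed in log space.
* **M step** — `pi` updates in closed form (`logit(mean(w))`, exact for an
  intercept-only zero model); the four NB coefficients maximize the
  `(1 - w)`-weighted NB log-likelihood by L-BFGS-B with the analytic gradient
  (digamma terms), warm-started at the previous iterate. After the first
  sweep the inner ascent is capped at a few quasi-Newton iterations; partial
  M-steps still increase the EM objective (generalized EM).
* **Convergence** — relative change of the EM objective Q below `epsilon`
  (default 1e-5), `max_iter` 200.

Starting values: `gamma` at the logit of the observed zero fraction, with a
`(k + 0.5)/(n + 1)` continuity correction at the 0/1 boundary; the NB
coefficients from a short fixed-dispersion (`kappa1 = 0`) EM pass started at a
log-linear regression on the positive counts.

Numerical choices that matter:

* **Centering.** All optimization uses the centered covariate
  `x - mean(x)`. With `x ~ 9-12` the intercept/slope pair is otherwise nearly
  collinear and quasi-Newton steps crawl along a ridge; slopes are
  centering-invariant, and intercepts are back-transformed on exit.
* **Admissible box.** Coefficients are box-constrained (centered scale):
  `beta0 in [-40, 40]`, `beta1 in [-15, 15]`, `kappa0 in [-10, 15]`,
  `kappa1 in [-3, 3]`. The dispersion bounds are deliberately tight relative
  to the mean bounds: depth effects on dispersion beyond `|kappa1| ~ 1` do
  not occur in data, while the unbounded likelihood can chase individual
  outliers into extreme dispersion-slope modes. The box is the model's
  declared parameter space; the reported maximum is the constrained MLE.
* **Final refinement.** After EM converges, a direct quasi-Newton pass on the
  *observed* log-likelihood (its coefficient gradient is the E-step-weighted
  complete-data gradient; the `gamma` gradient is `sum(w) - n*pi`) removes
  the slow terminal crawl of EM. A small set of additional refinement starts
  (heavy-tailed dispersion, near-zero inflation, nonzero dispersion slopes)
  guards against secondary modes; a full EM restart from a heavy-tailed start
  is triggered when the fit ends on the near-Poisson dispersion ridge. On
  small fixtures the result agrees with a multi-start direct maximization of
  the observed likelihood to better than 1e-3 log-likelihood units.
* **Q versus log-likelihood traces.** EM guarantees monotone *observed*
  log-likelihood; the across-iteration Q sequence is not monotone in general
  because the weights move. `TaxonFit` records both (`ll_trace` for the
  ascent property, `q_trace` for the convergence rule).

**Low-zero pre-processing.** Taxa with a zero fraction below 5% (configurable)
are fit as plain varying-dispersion NB regression with `pi = 0`: on nearly
zero-free data the structural/sampling split is not identifiable. Fits are
flagged rather than discarded when any optimizer step fails; all-zero taxa
must be removed beforehand by the prevalence filter (taxa kept only if
nonzero in strictly more than `min_nonzero_samples = 10` samples).

## Normalization

Normalized values are randomized quantile residuals at the fitted model:
`r_ij = Phi^{-1}(F(y_ij - 1) + u_ij f(y_ij))`, with `F`/`f` the fitted ZINB
(or NB) cdf/pmf, `u_ij ~ U(0,1)`, and the argument clamped to
`[1e-12, 1 - 1e-12]` so residuals stay finite. If the model is correct the
residuals are exactly standard normal and independent of depth. One uniform
draw per cell, in row-major (taxon, sample) order from a user seed: the same
seed reproduces the output bit for bit. A deterministic mid-quantile variant
(`u = 1/2`) is available. The NB cdf uses the regularized incomplete beta
function, verified against direct pmf summation to 1e-10.

## Diagnosis tests

Two nested likelihood-ratio tests, each fit per taxon and summed:

* **prevalence** — H0: `beta1_i = kappa1_i = 0` for all *i* (depth affects
  nothing); null fit is intercept-only with fixed dispersion.
* **equivalence** — H0: `beta1_i = 1, kappa1_i = 0` for all *i* (a single
  size factor per sample would suffice); the unit coefficient is imposed
  through the mean link with dispersion fixed.

Per taxon the statistic is `2(l_full - l_null)` with 2 df (clamped at zero;
nested models); the global statistic is the sum, chi-squared with `2p` df.
`gamma` is re-estimated under both nulls (the less restrictive reading).
Taxa whose full or null fit failed to converge are excluded from the global
sum with a warning and the df reduced; the per-taxon decomposition is
reported with BH-adjusted q-values as an additive convenience.

## Synthetic data

The generator emulates the validation study design. Library sizes are
uniform on `[a, b]` (default `[1e4, 1e5]`, typical 16S scale; the covariate
is their natural log), with an optional per-group multiplier (3x reproduces
the depth-confounded no-DA scenario). Per-taxon coefficients are drawn from
documented ranges — `beta0 ~ U(-12, 2)`, `beta1 ~ U(0.3, 1.6)` (the
heterogeneous-efficiency spread seen in real data), `kappa0 ~ U(-1, 2)`,
`kappa1 ~ U(-0.2, 0.5)`, `gamma ~ U(-3, 1)` — or loaded from a TSV template
so runs anchored to fits of real data can be reproduced. Counts are drawn
via the gamma-Poisson representation of the NB.

Two deliberate realism choices:

* **Prevalence–abundance coupling.** The zero-mass logit is tapered with
  expected abundance (`gamma - 8 * max(0, eta_center - log 30)`). Structural
  absence is a rare-taxon phenomenon; dominant community members are present
  in every sample. Without the coupling the generator produces abundant taxa
  with a few point-mass zeros — a regime real data does not produce, in which
  the <5% pre-processing rule classifies the taxon as NB and a structural
  zero among large counts destroys the chi-squared calibration of any
  likelihood-ratio test.
* **Null scenarios keep raw intercepts.** When a scenario pins `beta1` (and
  `kappa1`) — type I error studies, the no-effect half of power studies — the
  other coefficients are left exactly as drawn (`preserve_center=False`),
  mirroring how such scenarios are specified; if pinning raises a taxon's
  realized abundance, the zero-mass taper above is re-applied so the
  prevalence-abundance coupling keeps holding. For the equal-efficiency
  robustness scenario (`beta1 = 1` as a data-generating regime, not a null)
  intercepts are shifted by `(beta1_old - 1) * x_center` so taxa keep their
  abundance at the central depth.

Two-group designs assign exact halves after a seeded shuffle. A fraction
`da_fraction` of taxa get group log-fold-changes `beta2`: half up with
`exp(beta2) ~ U(lo, hi)`, half down with `1/exp(beta2) ~ U(lo, hi)` (each
half is `floor(da_fraction * p / 2)` taxa, for determinism). Columns that
come out empty (possible only for tiny sparse templates) are redrawn rather
than patched, so counts remain exact ZINB draws.

What the generator does **not** emulate: taxon-taxon correlation
(phylogenetic or ecological), batch effects, compositional closure (counts
are independent given depth; column sums only approximate the nominal
depth), and real abundance distributions (uniform coefficient ranges rather
than fits to a reference cohort). Passing tests therefore demonstrate
internal statistical correctness under the model, not performance on any
particular real dataset.

## Evaluation harness

Differential-abundance calling on normalized values: per-taxon two-sided
Wilcoxon rank-sum (midranks, tie-corrected normal approximation), BH
adjustment, calls at q <= 0.05. Power = TP/(TP+FN), FDR = FP/(TP+FP) with
0/0 counted as 0. The per-taxon "log fold-change" on residual-scale output
is the difference of group means (residuals can be negative, so a ratio is
undefined). TSS plus simplified, formula-level TMM- and CSS-like scalers are
included as labelled baselines; they claim no equivalence to the released
implementations.

## Study sizes and the depth covariate in calibration experiments

The acceptance script and the study-level tests run the full generative
pipeline at desk scale: 50-taxon panels (30 in the test suite), 100–1000
samples, and replicate counts of 200/120/40/10 for the four operating
characteristics (type I errors and powers of the two tests). These sizes are
the package's choice of a fast, reproducible study; rejection-rate estimates
carry the corresponding binomial Monte-Carlo error.

Calibration and evaluation experiments hand the fitter the *generating*
library sizes instead of recomputing depth as log column sums. With only
~50 synthetic taxa a single dominant taxon contributes a large share of
every column sum, so estimated depth carries that taxon's own noise (and,
in two-group designs, a group offset from the injected fold-changes); both
are artifacts of the small panel that vanish at real panel sizes (hundreds
of taxa), and both would contaminate a check whose purpose is the
calibration of the test or of the residual chain. The tool itself always
computes depth from the data. Consequence worth knowing: on very small
panels with strong dominance, depth estimated from column sums is noisy and
compositionally confounded, and downstream FDR can suffer — winsorizing or
excluding dominant taxa from the depth sum are reasonable practical
mitigations outside this package's scope.

## Known limitations

* The varying-dispersion LRT relies on chi-squared asymptotics; at n = 100
  the per-taxon statistic is mildly anticonservative in some regimes
  (near-Poisson taxa, very small counts), so the global test can run a few
  points above nominal on small panels.
* Zero-mass and dispersion estimates are noisy and can be biased at moderate
  n; only the mean-model coefficients (`beta0`, `beta1`) are reliably
  recovered. Downstream residuals are insensitive to this in practice.
* Winsorization of extreme counts is recommended before fitting very
  heavy-tailed taxa; not implemented here.
* No Bayesian shrinkage, no phylogenetic pooling, no longitudinal designs.
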