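# Methods

## Model and estimands

The package treats an herbivore's response (caterpillar relative growth rate,
RGR, per hour on the identity link; proportion herbivory on the logit link)
as a function f(x) of the toxin concentration x it ingests (nmol sinigrin per
mg leaf fresh weight). In a within-plant variation treatment the herbivore
faces two leaf doses, μ − δ and μ + δ. Two discrete dietary distributions
describe its intake: the counterfactual reference X_r with equal weight on
both doses (selectivity removed: both doses enter with the same overall mean
herbivory, which normalizes to ½/½), and the observed X_o with the doses
weighted by the measured mean proportion herbivory per dose level. The
estimands are

* Jr = E[f(X_r)] − f(E[X_r]) — the pure nonlinear-averaging (Jensen) effect;
  for small δ, Jr ≈ ½ δ² f″(μ), so the local second derivative f″ is the
  "Jensen potential";
* S = f(E[X_o]) − f(E[X_r]) — the pure selective-feeding effect, i.e. the
  benefit of ingesting a lower mean dose;
* JS = E[f(X_o)] − f(E[X_o]) − Jr — the interaction: the change in the
  Jensen effect caused by selectivity relocating and reshaping the diet;
* T̂ = Jr + S + JS, which collapses algebraically to E[f(X_o)] − f(E[X_r]);
* ε = T_o − T̂, the residual relative to the observed total effect T_o of the
  variability treatment. ε absorbs every mechanism the decomposition does
  not model, notably limits on physiological tracking of a fluctuating diet.

All quantities are reported in SD units of the link-scale response
(standardization by the pooled within-arm SD used for T_o), with equal-tailed
89% intervals — the reporting convention in this literature.

## Dose–response fitting

f is estimated from a separate dose-ladder experiment (10 log-spaced doses,
0.031–16.1 nmol/mg, 6 cages per dose) as a penalized natural cubic regression
spline on ln(dose), with knots at equally spaced quantiles of the observed
log doses and at most 4 basis functions plus an intercept — a deliberately
small basis that guards the second-derivative functionals against overfit
wiggles. The curvature penalty λ∫f″(z)²dz has null space {constant, linear in
log dose}, so exactly log-linear data are reproduced exactly; λ is selected
by generalized cross-validation on a fixed log-spaced grid, keeping the fit
deterministic. The natural-spline choice matters: at the same degrees of
freedom it carries three interior knots instead of one, roughly halving the
bias of fitted second differences for saturating (Hill-type) truth curves;
linear extension beyond the boundary knots also gives a well-defined
extrapolation, which is flagged with a warning on evaluation and refused (by
default) when a dietary distribution's support leaves the fitted dose range.

Uncertainty in f is a Gaussian approximation at the penalized optimum:
coefficient covariance σ̂²(XᵀX + λP)⁻¹ with σ̂² = RSS/(n − edf). Curve
realizations are multivariate-normal draws from it, reproducible by seed.
This stands in for posterior draws from a fully Bayesian smooth: it matches
the first two moments, runs at desk scale, and is exactly reproducible. The
heavier alternative (MCMC over a hierarchical GAM with covariate smooths) is
out of scope; covariates such as caterpillar pre-weight are generated as
inert columns by the simulator rather than entering the fit.

Hill curves f(x) = e0 + (emax − e0)xⁿ/(xⁿ + ec50ⁿ) are supported with
analytic evaluation and second derivatives (including the x → 0 limits: 0
for n > 2, 2Δ/ec50² at n = 2, −2Δ/ec50² at n = 1, divergent in between and
below). Smooth-curve second derivatives use central finite differences with
step 1e−4 of the dose-range width (configurable). The critical-consumption
threshold model m*(x) = k_crit/x expresses why marginal toxin increments
matter less at high mean dose: |dm*/dx| = k_crit/x² falls with x.

## Preference estimation

Selective feeding is estimated from the leaf-level herbivory table of the
within-plant variation cages: the point weight per dose level is the
back-transformed mean of logit herbivory (proportions first pulled off the
0/1 boundary by p ↦ (p(n−1) + 0.5)/n with n the dose-level group size; raw
means are available via `method="raw"`). Uncertainty is a plant-cluster
nonparametric bootstrap (plants resampled with replacement; the shrink
denominator is frozen at the observed group size so the resampling reduces
to a vectorized multinomial reweighting). This replaces a Bayesian mixed
model with plant random intercepts while preserving the estimand — mean
proportion herbivory per dose level under plant-level dependence — without
an MCMC dependency. Weights are passed unnormalized to the dietary module,
which normalizes them into probabilities; the relative preference is
reported as 100·(w_low − w_high)/w_high percent.

## Monte-Carlo propagation

The decomposition is evaluated on the full Cartesian cross of curve draws ×
preference draws (default 500 × 500 = 250,000 rows, curve-major). Jr depends
only on the curve draw; S, JS and T̂ also vary with the preference draw
through E[X_o]. Draws of the observed total effect T_o (cage-level bootstrap
of the standardized arm difference, SD held at its point estimate so
standardization is a fixed rescaling) are recycled across the cross; ε is
computed per row, and intervals can be produced with or without T_o
uncertainty (default: with). Draws with |T̂| < 1e−12 are excluded from the
per-mechanism share computation and counted; shares are summarized by the
median with quantile bounds because ratios of draws with T̂ near zero are
heavy-tailed.

## Synthetic experiments and what they do (not) show

The generator emulates the target experimental design: two cage-mean doses (0.66 and 1.89
nmol/mg) × {constant, within-plant variation} with 103 cages per arm, leaf
doses μ ± 0.61 nmol/mg, 7 leaves per plant (first painted leaf high, then
alternating), and a 10 × 6 dose ladder per response. Its generative model is
the analysis model: Hill truth curves on the link scale, Gaussian link-scale
observation noise, logit-normal leaf herbivory whose per-dose means are the
cage-level herbivory split by the feeding weights, and selectivity as a
one-parameter exponential-in-dose weighting w ∝ exp(−λ·dose) — the minimal
model that produces dose-dependent preference. Defaults are calibrated once
to the magnitudes the field reports and then held fixed: λ = ln(2.06)/(2·0.61)
≈ 0.592 reproduces a 106% preference for the lower-dose leaf across the
1.22 nmol/mg within-plant gap; the RGR truth curve Hill(e0 = 0.020,
emax = 0.005, ec50 = 1.0, n = 2) per hour with noise SD 0.019 makes the
high-vs-low mean contrast ≈ −0.38 SD and leaves the ladder dose–response
detectable but noisy; herbivory runs from 35% down to 6% (ec50 = 1.5,
n = 1.5) with logit noise 0.9. Note that with exponential-in-dose weighting
the preference *ratio* is the same at both cage means (it depends only on
the dose gap); the simulator therefore does not reproduce mean-dependent
selectivity strength, a qualitative feature reported for this system.

Because the generator draws independent Gaussian noise per cage and couples
covariates to nothing, passing recovery tests demonstrate correctness of the
estimation machinery under the model's own assumptions — not robustness to
confounded covariates, overdispersion, leaf-position effects, or behavioral
feedbacks present in real cage experiments.

Ground truth (exact Jr/S/JS/T̂ per response × mean level) comes from
closed-form Hill evaluation at the two treatment doses. Recovery is assessed
as 89%-interval coverage over 50 replicate experiments at the design sizes;
measured coverage for (Jr, S, JS) of the RGR response at the high mean is
84/92/94% (seed 1). Coverage for Jr is intrinsically delicate: a
4-basis-function global smooth cannot match the local second difference of a
sigmoid exactly, leaving a projection bias of order half the sampling SE at
the high mean — and substantially more at the low mean, where the two-point
support reaches toward the sparse low-dose end of the ladder. Low-mean Jr
estimates from this pipeline (and from any similarly df-capped smooth)
should be read as qualitative.

## Numerical choices and conventions

* Monte-Carlo depth for reported summaries: 500 × 500; recovery testing uses
  200 × 200 per replicate, which leaves interval endpoints essentially
  unchanged while keeping 50 replicates fast.
* Intervals are equal-tailed percentile intervals of the draws (ci_level
  0.89 by default; the CLI labels the bounds q0.055/q0.945).
* Hill evaluation uses the overflow-safe ratio (x/ec50)ⁿ parameterization;
  doses must be nonnegative, and smooth curves (log-dose basis) reject
  dose 0.
* Two-point distributions whose offset underflows (μ − δ == μ + δ in floats)
  degrade to a point mass rather than violating support distinctness.
* Degenerate preference data (all-zero herbivory on both levels) fall back
  to equal weights with a warning; a single plant is an error (no cluster
  variance is estimable).
* All randomness flows through integer seeds: the pipeline spawns
  independent streams for curve draws, preference bootstrap and cage
  bootstrap from one master seed; the CLI records seeds in a manifest, and
  identical seeds give byte-identical simulated tables.

## Known limitations

* The Gaussian curve approximation ignores smoothing-parameter uncertainty
  and any non-Gaussianity a full posterior would carry.
* T_o standardization holds the pooled SD at its point estimate inside the
  bootstrap; SD uncertainty is not propagated.
* The decomposition is defined for finite dietary supports (here two doses);
  continuous intake dynamics, induction lags and movement behavior are out
  of scope.
* Pupation rate is generated by neither module and never decomposed; the
  dose ladder covers RGR and herbivory only.
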