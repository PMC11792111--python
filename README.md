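# toxvar

Does variability in a plant's chemical defense help or hurt the herbivores
feeding on it? The answer depends on at least three mechanisms that act at
once: **nonlinear averaging** (Jensen's inequality — a varying toxin dose fed
through a curved dose–response function shifts the *average* response),
**selective feeding** (the herbivore eats more of the less-defended tissue,
shifting its realized dietary dose), and their **interaction** (selectivity
relocates the diet to a differently curved region of the dose–response).
`toxvar` implements a counterfactual-simulation method that partitions the
effect of within-plant toxin-dose variability on herbivore responses into
exactly these pieces, plus a residual that captures everything else (e.g.,
limits on how fast an herbivore's detoxification physiology can track a
fluctuating diet).

It is written for quantitative ecologists running mean × variance experiments
— e.g., *Arabidopsis thaliana* painted with sinigrin (a glucosinolate, doses
in nmol per mg leaf fresh weight) and fed to *Trichoplusia ni* caterpillars —
but the machinery is generic: any saturating dose–response, two-point dietary
dose distribution, and cage-style experiment fits.

## The decomposition

Let f(x) be the dose–response function on its link scale (identity for
caterpillar relative growth rate, RGR; logit for proportion herbivory). Let
X_r be the dietary dose distribution an unselective herbivore would
experience (the two painted doses μ ± δ, equally weighted) and X_o the
observed distribution (the same doses weighted by measured herbivory per dose
level). Then

    Jr := E[f(X_r)] − f(E[X_r])          nonlinear averaging
    S  := f(E[X_o]) − f(E[X_r])          selective feeding (mean shift)
    JS := E[f(X_o)] − f(E[X_o]) − Jr     interaction
    T̂  := Jr + S + JS                    predicted total effect of variability
    ε  := T_o − T̂                        residual (unmodeled mechanisms),

where T_o is the observed total effect: the variable-minus-constant treatment
arm difference in mean link-scale response, standardized by its pooled SD.
The identities T̂ = E[f(X_o)] − f(E[X_r]) and T_o = T̂ + ε hold exactly, per
Monte-Carlo draw. Uncertainty in f (Gaussian draws around a penalized
natural-spline fit on log dose, ≤ 4 basis functions + intercept) is crossed
with uncertainty in the preference weights (plant-cluster bootstrap):
500 × 500 = 250,000 simulations, summarized by means and equal-tailed 89%
intervals.

A synthetic-experiment generator (`toxvar.simulate`) produces cage, leaf and
dose-ladder tables with the same structure the analysis assumes — known Hill
truth curves, known exponential-in-dose selectivity, Gaussian link-scale
noise — together with the exact Jr/S/JS implied by the truth, so the whole
pipeline is testable end to end without any external data.

## Worked example

```python
import pandas as pd
from toxvar import SimulationConfig, generate_variation_experiment, \
    generate_dose_ladder_experiment, fraction_of_predicted
from toxvar.pipeline import decompose_experiment

cfg = SimulationConfig(seed=20260927)        # 103 cages/arm, 10x6 ladder
cages, leaves, truth = generate_variation_experiment(cfg)
ladder = generate_dose_ladder_experiment(cfg, "rgr")
res = decompose_experiment(cages, leaves, ladder, response="rgr",
                           mean_treatment="high", mu=1.89, delta=0.61, seed=815)
print(res.summaries.round(4))
```

prints (SD units of the link-scale response, 89% intervals):

```
  quantity    mean   lower   upper
0       jr -0.0225 -0.0642  0.0174
1        s -0.0338 -0.1043  0.0382
2       js  0.0019 -0.0022  0.0062
3    t_hat -0.0544 -0.1544  0.0507
4    t_obs  0.0084 -0.2237  0.2447
5      eps  0.0629 -0.1886  0.3167
```

Here the high-mean dose–response is nearly flat, so all three mechanisms are
weak (intervals cover zero) and the observed effect of variability is
statistically indistinguishable from the predicted one. At the low mean the
same pipeline finds a large positive Jr — variability sits on the convex
part of the fitted curve — and a significantly negative residual ε.

As a command-line tool the same pipeline is:

```bash
toxvar simulate --out ds/ --seed 9
toxvar decompose --dataset ds/ --response rgr --mean-level high --out out/
toxvar report out/summary_rgr_high.csv
```

The numbered drivers under `analysis/` run the full narrative
(01 simulate → 02 fit curves → 03 estimate preference → 04 decompose →
05 report), writing tables under `results/`.

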