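# trawlsel

Size-selectivity and motion analysis for trawl codends, built around the
covered-codend experiment: a fine-mesh cover placed over a codend catches
every fish that escapes through the codend meshes, so the probability that
a fish of length *l* is retained, *r(l)*, is estimable as a binomial
proportion per 1-cm length class.  The package is aimed at fisheries
scientists evaluating gear modifications (mesh geometry, stimulating
devices such as a "shaking" canvas) that are meant to reduce the capture
of undersized fish.

## What it computes

**Selection curves.** Eight retention models: the classical sigmoids
Logit, Probit, Gompertz and Richard, parameterised by L50 (length at 50%
retention) and SR = L75 − L25, the Richard family adding an asymmetry
parameter 1/δ; and their contact-probability variants

&nbsp;&nbsp;&nbsp;&nbsp;*r(l) = 1 − C + C · base(l | L50꜀, SR꜀)*,

where *C* ∈ (0, 1] is the length-independent probability that a fish
contacts the meshes in a way that permits length-dependent escape.  Fish
that never make such contact are retained, putting a floor of 1 − C under
the curve.

**Estimation.** Hauls are pooled and parameters maximise the raised-count
binomial log-likelihood

&nbsp;&nbsp;&nbsp;&nbsp;−Σⱼ Σₗ { nRⱼₗ/qRⱼ · ln r(l) + nEⱼₗ/qEⱼ · ln(1 − r(l)) },

with nR/nE the codend/cover counts measured in haul *j* and class *l*,
and qR/qE the compartment subsampling ratios.  Models are ranked by AIC;
fit quality is tested by deviance against the saturated model on
(occupied classes − k) degrees of freedom.

**Uncertainty.** A double bootstrap — hauls resampled with replacement
(between-haul variation), then each selected haul's measured fish
resampled (within-haul variation), then refit — yields Efron percentile
95% confidence intervals per length and per parameter.  Two gears are
compared with the delta curve Δr(l) = r_e(l) − r_c(l), whose CIs come
from index-paired replicates of the two independent bootstrap
populations; lengths where the CI excludes 0 differ significantly.

**Codend motion.** From 1-Hz depth and tri-axial acceleration records:
total acceleration TA = √(X² + Y² + Z²), peak/valley detection with a
plateau-midpoint tie rule, peak-to-peak amplitude, amplitude ratio
(excursion / side-panel length, default 99.6 cm), oscillation period,
stable-depth segmentation (≤ 0.5 m depth change) for at-sea records, and
OLS trends against flow velocity.

**Synthetic data.** Generators for catch datasets (known selection curve,
optional contact stage and between-haul L50 jitter, compartment
subsampling) and drifting/oscillating/noisy depth traces, so every stage
is testable against known ground truth.

## Worked example

```python
import numpy as np
from trawlsel import *

# two synthetic gears: a more selective experimental codend vs a control
ds_e, _ = simulate_catch(CatchSimConfig(params=ParamVector(22.0, 4.0),
                         n_hauls=4, fish_per_haul=600, treatment="exp", seed=1))
ds_c, _ = simulate_catch(CatchSimConfig(params=ParamVector(19.0, 4.0),
                         n_hauls=6, fish_per_haul=600, treatment="ctl", seed=2))

best_e, table = select_model(fit_all(ds_e))
print(table[["model", "k", "aic", "delta_aic", "l50", "sr"]].head(3).round(2))
print(f"best: {best_e.spec.name}, L50 = {best_e.params.l50:.1f} cm, "
      f"SR = {best_e.params.sr:.1f} cm, GOF p = {best_e.p_value:.2f}")

best_c, _ = select_model(fit_all(ds_c))
grid = np.arange(13.0, 42.0, 0.1)
pop_e = double_bootstrap(ds_e, best_e.spec, n_boot=500, seed=11, grid=grid, point_fit=best_e)
pop_c = double_bootstrap(ds_c, best_c.spec, n_boot=500, seed=12, grid=grid, point_fit=best_c)
print("L50 95%% CI: (%.1f, %.1f) cm" % efron_ci(pop_e)["params"]["l50"])

res = delta_curve(pop_e, pop_c, best_e, best_c)
print("significant ranges (cm):",
      [(round(a, 1), round(b, 1)) for a, b in res.significant_ranges])
```

Output:

```
     model  k      aic  delta_aic    l50    sr
0    Logit  2  2243.54       0.00  22.06  4.00
1   Probit  2  2244.60       1.05  22.07  4.22
2  Richard  3  2245.35       1.81  22.03  4.00
best: Logit, L50 = 22.1 cm, SR = 4.0 cm, GOF p = 0.89
L50 95% CI: (21.9, 22.3) cm
significant ranges (cm): [(13.0, 41.9)]
```

The AIC table ranks the model families; the true Logit generator wins and
the extra Richard parameter costs ~2 AIC as expected.  The fitted L50
(22.1 cm, truth 22.0) sits inside its bootstrap CI, and the delta curve
flags the experimental gear's retention as significantly lower across the
whole observed range — its selection curve is shifted 3 cm to the right
of the control's.

The same pipeline is scriptable from the shell:

```sh
trawlsel fit --data catch.csv --treatment shaking --models all --out fits.json
trawlsel bootstrap --data catch.csv --treatment shaking --model richard \
         --nboot 1000 --seed 42 --out pop.json
trawlsel motion --depth depth.csv --panel-cm 99.6 --trim sea --out motion.json
trawlsel pipeline --config pipeline.yaml --out-dir results/
```

Every stochastic command requires an explicit seed and writes a run
manifest for bit-exact reproduction.

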