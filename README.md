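# ndes — forest species-composition dynamics on the abundance simplex

`ndes` models the long-run change in tree-species composition of a large
forest region from permanent-plot inventory data. It is aimed at forest
biometricians and ecologists working with continuous-inventory panels
(plots remeasured on a fixed cycle) who want to ask: *where is the
composition heading, and could a species group disappear?*

The motivating system is the subtropical forest of southeastern China,
where tree species are managed as three groups — pine, fir, and
broadleaf — and each plot's composition is summarized by the **abundance
triple** $Y = (y_1, y_2, y_3)$, the biomass share of each group
($y_i \ge 0$, $\sum_i y_i = 1$).

## The model

A nonlinear difference equation system (NDES) sends the composition at
one survey to the composition one 5-year interval later,
$Y_{k+1} = F(Y_k)$, with

$$
F(Y)_i = \frac{w_i}{w_1 + w_2 + w_3},\qquad
w_1 = 1,\quad
w_2 = t_1 e^{t_3 y_1 + t_4 y_2},\quad
w_3 = t_2 e^{t_5 y_1 + t_6 y_2},
$$

a six-parameter softmax-type map whose outputs automatically stay on the
simplex. The package provides:

- **abundance** — species-to-group classification, biomass-share
  abundance, pairing of surveys into 5-year reexamination periods,
  dominant-group tallies;
- **core** — the map itself (plus a literal term-by-term transcription
  used as an internal cross-check), trajectories, and a multi-start
  fixed-point solver for the equilibrium ("limit") $Y^* = F(Y^*)$;
- **estimation** — nonlinear least squares for $t_1..t_6$ with per-group
  $R^2$ and a Gauss–Newton parameter covariance;
- **inference** — Monte Carlo covariance of the limit (one parameter
  draw per plot), truncated-normal confidence intervals on $[0,1]$, and
  a Hotelling-style F-test of extinction hypotheses on the first two
  limit components;
- **prediction** — long-horizon projection by iterating every plot and
  averaging per step (iterate-then-average);
- **synthetic** — an inventory-panel generator with known ground truth
  (Dirichlet observation noise, mixture-of-dominance initial plots), so
  the whole pipeline is testable without restricted inventory data.

A `ndes` command-line tool wraps the pipeline
(`simulate`, `fit`, `predict`, `limit`, `intervals`, `ftest`, `tally`).

## Worked example

Simulate one 1712-plot reexamination period under the default ground
truth, refit the model, and analyse its limit:

```python
import numpy as np
from ndes import (SyntheticConfig, generate_plot_pairs, fit_ndes,
                  fixed_point, mc_limit_covariance, truncnorm_interval,
                  extinction_test_battery)

cfg = SyntheticConfig(n_plots=1712, seed=42)
pairs = generate_plot_pairs(cfg)
fit = fit_ndes(pairs)
print("fitted parameters:", np.round(fit.T.to_array(), 4))
print("R^2 (pine, fir, broadleaf):", np.round(fit.r2, 3))
lim = fixed_point(fit.T)
print("limit Y*:", np.round(lim.y_star, 4))
est = mc_limit_covariance(fit, [p.y1 for p in pairs], seed=42)
for i, g in enumerate(("pine", "fir", "broadleaf")):
    iv = truncnorm_interval(float(est.y_star[i]),
                            float(np.sqrt(est.sigma_star[i, i])), 0.95)
    print(f"{g:9s} 95% CI [{iv.lower:.4f}, {iv.upper:.4f}]")
for name, t in extinction_test_battery(est).items():
    print(f"{name:13s} F = {t.F:9.2f}  p = {t.p_value:.2e}")
```

Output:

```
fitted parameters: [ 1.5486 33.8562 -3.4486  2.7486 -5.562  -2.9399]
R^2 (pine, fir, broadleaf): [0.935 0.932 0.948]
limit Y*: [0.0399 0.0643 0.8958]
pine      95% CI [0.0366, 0.0432]
fir       95% CI [0.0595, 0.0690]
broadleaf 95% CI [0.8887, 0.9030]
pine_extinct  F =    410.34  p = 2.79e-146
fir_extinct   F =    537.39  p = 8.23e-182
both_extinct  F =    405.07  p = 9.86e-145
```

Reading it: the refitted parameters are close to the generating ones
(the true $t_1..t_6$ are 1.5110, 33.1472, −3.3836, 2.8001, −5.5520,
−2.8888), the equilibrium composition is roughly 4% pine, 6% fir, 90%
broadleaf — broadleaf dominance is the attractor — and every extinction
hypothesis (pine share → 0, fir share → 0, both → 0) is overwhelmingly
rejected: the conifer groups decline to a small but nonzero share.

The same analysis from a shell:

```sh
ndes simulate --seed 42 --n-plots 1712 --out plots.csv
ndes fit plots.csv --period 2014 2019 --out fit.json
ndes limit fit.json
ndes intervals fit.json plots.csv --period 2014 2019 --seed 42
```

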