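# Methods

This note records the model, the numerical and statistical choices, and
what the synthetic-data tests do and do not establish.

## The map and its state space

The state is the abundance triple $Y=(y_1,y_2,y_3)$ of the pine, fir
and broadleaf groups: biomass shares of a plot, a point on the
2-simplex. One application of the map

$$F(Y)_i = w_i / \textstyle\sum_j w_j, \qquad
w_1 = 1,\; w_2 = t_1 e^{t_3 y_1 + t_4 y_2},\; w_3 = t_2 e^{t_5 y_1 + t_6 y_2}$$

advances a plot by one 5-year survey interval. Because only ratios of
the weights matter, the first weight is fixed at 1; $t_1, t_2 > 0$ are
required (they scale the fir and broadleaf weights, and the equivalent
reciprocal form divides by them), while $t_3..t_6$ are unconstrained
exponents per unit abundance. The implementation subtracts the largest
log-weight before exponentiating (the standard log-sum-exp shift), which
is algebraically exact and keeps arbitrary Monte Carlo parameter draws
from overflowing. A term-by-term transcription of the three reciprocal
expressions (`step_literal`) is kept solely as an independent oracle;
the two forms agree to 1e-12 over randomized inputs with
$t_1,t_2 \in (0.01, 100)$ and exponents in $(-10, 10)$.

Outputs are strictly interior to the simplex, so a trajectory can touch
a boundary only at its starting point.

## Fixed points ("limits")

The equilibrium $Y^* = F(Y^*)$ is interpreted as the ultimate
composition under the current dynamics. It is found by plain Picard
iteration $Y \leftarrow F(Y)$ to a tolerance of 1e-12 on the maximum
component change (cap $10^6$ iterations), with damped iteration
$Y \leftarrow (Y + F(Y))/2$ as an automatic fallback when the residual
is non-monotone over a 100-iteration window — a guard for pathological
parameter draws during Monte Carlo, not needed at fitted values.

Global uniqueness of the equilibrium is an assertion, not a theorem, so
the solver verifies it per call from 16 starts (the three vertices, the
barycenter, and 12 seeded random interior points) and raises an error
listing the distinct limits if they disagree beyond 10× the tolerance.

This check earns its keep: dense-grid iteration (231 starts) shows that
the fitted parameter sets of the two earliest reexamination periods
(1989–1994 and 1994–1999) each possess **three** stable equilibria —
one per dominant group (for 1989–1994: pine-dominant
(0.886, 0.064, 0.050), fir-dominant (0.054, 0.925, 0.021), and
broadleaf-dominant (0.039, 0.028, 0.934)). For those maps the realized
limit depends on the basin containing the data, and the solver reports
the multiplicity rather than choosing silently. The four post-1999
parameter sets have a single global attractor; the 2014–2019 map's is
(0.0408, 0.0642, 0.8950).

## Parameter estimation

For each plot of a reexamination period the former triple $Y_0$ and
latter triple $Y_1$ are observed. The fit minimizes
$\sum_{\text{plots}} \sum_{i=1}^{3} (y_{i1} - F(Y_0)_i)^2$ over
$(\log t_1, \log t_2, t_3..t_6)$ — the log scale enforces positivity —
using Levenberg–Marquardt with an analytic softmax Jacobian, with up to
five seeded 10%-jittered restarts on optimizer failure.

Starting values exploit the exact identities
$\log(y_{21}/y_{11}) = \log t_1 + t_3 y_{10} + t_4 y_{20}$ and
$\log(y_{31}/y_{11}) = \log t_2 + t_5 y_{10} + t_6 y_{20}$: two ordinary
linear regressions recover the parameters exactly on noiseless data.
Only this initializer floors latter components (at 1e-6) before taking
ratios; the least-squares loss keeps observed zeros as-is.

Per-group $R^2$ is $1 - SSE_i/SST_i$ about the observed group mean. A
group whose observed values are all identical has no defined $R^2$ and
is reported as missing (NaN), never as 0 or 1.

**Parameter covariance.** Residual triples sum to zero plot-wise (both
observed and predicted triples sum to one), so only two residual
components per plot are informative; using all three would make the
information matrix singular. The covariance is Gauss–Newton on the first
two components: $\hat\sigma^2 (J^\top J)^{-1}$ with
$\hat\sigma^2 = RSS_2/(2n - 6)$ (two informative residuals per plot, six
parameters; the degrees of freedom per plot are configurable), computed
on the optimization scale and mapped back to the $t$ scale by the delta
method ($\partial t_i/\partial \log t_i = t_i$ for $i=1,2$). The
residual model is homoscedastic; under the Dirichlet noise of the
synthetic generator (variance $\propto p(1-p)$) this is mildly
conservative — 3-standard-error coverage of the true parameters measured
over 100 seeded replicates at $n=1500$ is ≈100%, comfortably above the
93% working threshold.

## Uncertainty of the limit

**Monte Carlo covariance.** With fitted parameters $T$ and covariance
$\Sigma$, one parameter vector $T^0 \sim \mathcal N(T, \Sigma)$ is drawn
per plot (Cholesky factor when $\Sigma$ is full rank, eigenvalue square
root otherwise; single seeded generator, fixed draw order), and the map
is iterated with $T^0$ from that plot's latter observed abundance. The
sample covariance $\Sigma^*$ of the $n$ simulated limits estimates the
limit's dispersion. Because each simulated limit is an attractor of its
own map, the per-plot initial value does not move it — $\Sigma^*$ is a
pure parameter-uncertainty propagation, and the per-plot draw scheme is
retained for fidelity to the published procedure (a draws-per-plot
multiplier exists for variance-of-variance diagnostics). Draws with
$t_1^0 \le 0$ or $t_2^0 \le 0$, where the map is undefined, are redrawn
up to 100 times and counted; if more than 10% of draws need redraws the
covariance is declared too wide for the positivity constraint and the
run errors out. Simulated limits sum to one, so all row, column and
total sums of $\Sigma^*$ vanish (to 1e-10 in floating point) and
$\Sigma^*$ has rank 2.

**Truncated-normal intervals.** A limit component lives in $[0,1]$, so
its interval uses the normal density restricted and renormalized to that
interval. Intervals are central (equal tail mass $(1-\text{level})/2$ on
each side); quantiles come from the truncated CDF (scipy's `truncnorm`,
whose `ppf` performs the root-finding). Equal-tail was chosen over
highest-density because published interval tables for this analysis are
near-symmetric about the point estimate. When a published interval must
be inverted for its implied $\sigma$, one $\sigma$ cannot in general hit
both endpoints of a truncated interval, so $\sigma$ is root-found to
match the interval *width* (strictly increasing in $\sigma$); with this
calibration the package reproduces the published 99% endpoints from the
95% intervals to better than 5e-4.

**Extinction F-test.** $\Sigma^*_{3\times3}$ is rank-2, so hypotheses
about the limit vector are tested on the first two (pine, fir)
components: $F = \frac{n-p}{(n-1)p}\, d^\top S^{-1} d$ with $d$ the
difference from the hypothesized pair, $S$ the top-left 2×2 block of
$\Sigma^*$, $p=2$, referred to $F(p, n-p)$. The three standard
hypotheses are pine → 0 (fir unchanged), fir → 0 (pine unchanged), and
both → 0. P-values are reported to six decimals in the CLI output.

## Long-term projection

Projection iterates **each plot separately** from its latter observed
abundance and averages across plots at each 5-year step
(iterate-then-average). The map is nonlinear, so averaging initials
first gives a different series; a regression test pins the order. The
default horizon is 2119. The signed relative error of a prediction is
$100\,(\hat y - y)/y$ per component, undefined (NaN) where the actual
value is zero.

## The synthetic generator

The generator emulates a continuous-inventory panel:

- **Initial plots**: a three-component Dirichlet mixture, one component
  per dominant group, component means (0.60,0.25,0.15), (0.20,0.60,0.20),
  (0.15,0.20,0.65) with concentration 12, mixed with weights
  478 : 402 : 832 — the dominance mix of the most recent survey. This
  spreads plots over all three dominance basins while keeping each plot
  recognizably dominated by one group.
- **Dynamics + noise**: the latter abundance is Dirichlet with mean
  $F(Y_0)$ and concentration $\kappa$ — mean-correct, simplex-valued,
  one dispersion knob. $\kappa=\infty$ (exact mode) is available for
  zero-noise recovery tests. The default $\kappa = 50$ was calibrated
  once so that per-period fit $R^2 \approx 0.93$, inside the 0.81–0.98
  range reported for real inventory periods; this calibration is
  heuristic, since the real observation-noise magnitude is unknown.
- **Ground truth**: the fitted 2014–2019 parameters by default, so
  synthetic runs are commensurate with the current forest.
- **Panel features**: configurable number of surveys at 5-year spacing,
  and a drop fraction removing plots between surveys to emulate
  relocated plots that cannot be paired (historically about one third).
- **Tree level**: per-plot tree lists with species names drawn from the
  group lists and positive random biomasses rescaled so group shares hit
  the plot's target abundance exactly. This is plumbing to exercise the
  classification/abundance path end to end; it is *not* an allometric
  model — no DBH, height, or size structure.
- **Seeding**: one master seed; every stage spawns its own child
  generator via `numpy.random.SeedSequence.spawn`, so any stage is
  reproducible in isolation.

What passing synthetic tests show: the estimator is consistent and its
covariance usable under mean-correct simplex noise; the Monte Carlo /
interval / test machinery is internally coherent (95% limit intervals
cover the true limit in ≥ 90% of 200 seeded end-to-end replicates at
$n=200$ plots). What they do not show: robustness to the features real
inventories add — spatially correlated disturbance, measurement-protocol
changes between surveys, heteroscedastic or biased biomass estimation,
and plot-relocation patterns that are not missing-at-random.

## Numerical details and degenerate inputs

- Abundance triples must sum to 1 within 1e-9 on input; computed
  abundances sum to 1 within 1e-12.
- Dominance ties are resolved by the fixed priority pine > fir >
  broadleaf and counted, so tallies are reproducible.
- A plot with zero total biomass has undefined abundance: excluded from
  pairing (counted), an error if forced through `compute_plot_abundance`.
- Unknown species names are an error naming the species, never a silent
  assignment to broadleaf.
- Duplicate (plot, year) rows are an error; pairing is strict on exact
  endpoint years; the survey interval (default 5) is configurable.
- Problem sizes in the test suite — e.g. 100 replicates at n = 1500 for
  the coverage study, 200 end-to-end replicates at n = 200 for interval
  coverage, 500 draws for the Monte Carlo oracle comparison — were
  chosen as the smallest sizes at which the statistical assertions are
  stable across seeds.

## Known limitations

- Three species groups only; the weight structure generalizes, the code
  does not.
- No analytic stability classification (Jacobian eigenvalues);
  uniqueness/stability is established empirically per parameter set by
  multi-start agreement, which is what surfaced the early-period
  multiple equilibria.
- The least-squares objective treats all components and plots equally;
  no Dirichlet/multinomial likelihood, weighting, or robustness options.
- The F-test requires $\Sigma^*_{2\times2}$ to be invertible and
  inherits the normal approximation of the Monte Carlo limits.
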