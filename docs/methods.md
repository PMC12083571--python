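# Methods

## Models

Both the analysis model and every imputation model are one-level
random-intercept GLMMs. Two families are supported: gaussian with identity
link (constant variance) and binomial with logit link (variance
$\mu(1-\mu)$, dispersion fixed at 1). The site random intercept is the
only random effect; random slopes, nested or crossed factors, and
non-canonical links are out of scope.

## PQL estimation from summaries

PQL replaces the GLMM by a sequence of weighted working linear mixed
models. At state $(\beta, \hat v)$ the working response and weights are

* gaussian: $z = y$, $w = 1$ (the linearization is exact);
* binomial: $z = \eta + (y-\mu)/(\mu(1-\mu))$, $w = \mu(1-\mu)$, with
  $\mu$ clipped to $[10^{-6}, 1-10^{-6}]$ so working responses stay finite
  without materially moving estimates at realistic sample sizes.

The working LMM has per-site marginal covariance
$\Sigma_i = \phi W_i^{-1} + \sigma_u^2 \mathbf{1}\mathbf{1}^\top$. By the
Woodbury identity every REML quantity reduces to functions of the site
Gram matrices $[X \mid z \mid 1]^\top W_i [X \mid z \mid 1]$ plus row
counts — the only payload a site ever shares. Writing
$\lambda = \sigma_u^2/\phi$ and $k_i = \lambda/(1+\lambda w_{i+})$:

* $X^\top\Sigma^{-1}X = (\sum_i X_i^\top W_i X_i - \sum_i k_i c_i
  c_i^\top)/\phi$ with $c_i = X_i^\top W_i \mathbf{1}$, and analogous
  rank-one corrections for the right-hand side and the residual quadratic
  form;
* $\log|\Sigma_i| = n_i\log\phi + \log(1+\lambda w_{i+}) - \log|W_i|$,
  whose last term does not involve the variance parameters and is dropped.

The REML criterion is profiled down to the single parameter $\lambda$
($\phi$ profiled analytically for gaussian, held at 1 for binomial —
classical PQL; binary imputation needs no residual draw) and minimized by
bounded scalar search on $\log\lambda \in [-18, 18]$ with tolerance
$10^{-9}$. The lower bound and exact-$\lambda=0$ limit are compared
against the interior optimum; ties within $10^{-6}$ relative are resolved
to $\sigma_u^2 = 0$ (with a single site the profile is flat in $\lambda$
— intercept and random intercept are confounded — and the boundary is the
defined estimate). A boundary estimate is a valid result, not an error.
`cov_beta` is the GLS covariance at the variance optimum; no
variance-estimation uncertainty is propagated into it, matching the use
of $\widehat{\mathrm{Var}}(\hat\gamma)$ as the draw covariance.

REML (not ML) was chosen for the working LMM: it matches standard
mixed-model practice, the closed-form balanced one-way ANOVA solution
($\hat\sigma_e^2 = \mathrm{MSE}$, $\hat\sigma_u^2 =
\max(0,(\mathrm{MSA}-\mathrm{MSE})/n)$) used as a test oracle, and
`statsmodels`' `MixedLM(reml=True)`, the independent cross-check in the
gaussian tests.

BLUPs are the one-dimensional shrinkage estimates
$\hat v_i = \sigma_u^2 w_{i+}\bar r_i/(\phi + \sigma_u^2 w_{i+})$ with
conditional variance $\tau_i = (1/\sigma_u^2 + w_{i+}/\phi)^{-1} \le
\sigma_u^2$, both computable from a site's summary alone; a site with no
eligible rows gets the prior $(0, \sigma_u^2)$, and $\sigma_u^2 = 0$
gives the defined limit $(0, 0)$.

## The outer loop and the federated protocol

The gaussian working model does not depend on the current state, so one
REML solve is the converged fit and the federated protocol needs exactly
one summary round per site. For binomial, the loop is initialized with
$\beta$ from a no-random-effect GLM (one IRLS pass from $\eta = 0$) and
BLUPs at 0, then iterates linearize → solve → update-BLUPs until the
maximum absolute parameter change falls below $10^{-6}$ or the round
budget is exhausted (a fit that stops on the budget is flagged
unconverged, not an error). The default budget is one mixed-model round —
the communication-efficient mode; `fit_rounds=50` gives the fully
converged (centralized-equivalent) reference. The binomial initialization
requires one extra summary exchange (at $\eta = 0$); it is logged
separately from the mixed-model rounds, so the audit log shows
$L \times$ rounds "fit" payloads plus $L$ "init" payloads for binomial
fits and no init payloads for gaussian fits.

Aggregation is summation of Gram matrices, so the federated fit equals
the pooled fit to floating-point rounding — the pooled and federated
entry points literally share the solver, and the test suite verifies
agreement to $10^{-8}$ over randomized federations. BLUP updates are
computed at the aggregator and returned only to the owning site. The
federation is simulated in-process; transport, encryption and dropout
handling are deliberately out of scope — the protocol's mathematics, not
networking, is the subject. Sites with fewer than 2 rows still contribute
valid summaries and are only flagged in logs.

## Multiple imputation

For each incomplete covariate the imputation GLMM is fitted on the rows
where that covariate is observed, using current filled values of the
other columns; rows where it is missing are imputed. Draws:

* $\gamma^* \sim \mathrm{MVN}(\hat\gamma, \widehat{\mathrm{Var}}(\hat\gamma))$;
* gaussian targets: $\phi^* = \hat\phi\, d/\chi^2_d$ with $d = n_{\text{fit}} - q$;
* $\sigma_v^{2*} = \hat\sigma_v^2 (L-1)/\chi^2_{L-1}$ — a scaled
  inverse-$\chi^2$ with degrees of freedom tied to the number of sites,
  the standard approximation in multilevel-imputation practice; the exact
  form is a genuinely open design point and is isolated in one function;
* $v_i^* \sim N(\hat v_i, \tau_i)$ per site, preserving site-specific
  information (drawing fresh intercepts from $N(0, \sigma_v^{2*})$ would
  discard exactly the signal the method exists to keep);
* $\hat\sigma_v^2 = 0$ degenerates all random-intercept draws to 0, and a
  single-site federation forces $\sigma_v^{2*} = 0$ with a warning.

Imputed values are $\eta + N(0, \phi^*)$ (gaussian) or
$\mathrm{Bernoulli}(\mathrm{expit}(\eta))$ (binary) with
$\eta = Z\gamma^* + v^*_{\text{site}}$.

Chained equations: masked cells are first hot-deck filled by sampling
with replacement from the same site's observed values (global pool as
fallback for an all-missing site — a site-stratified start preserves
site-level structure from the first sweep), then `between_iterations`
sweeps visit the incomplete columns in order of increasing missing
fraction. Randomness derives from one root seed via counter-based
`SeedSequence` spawn keys per (imputation $m$, sweep, column), so dataset
$m$ is fully determined by $(seed, m)$, results do not depend on
evaluation order, and raising $M$ leaves earlier datasets unchanged.

## Analysis and pooling

Each completed dataset is analyzed with the analysis GLMM through the
same federated engine (exact in one round for gaussian outcomes). Pooling
follows Rubin's rules: $\bar Q$ = mean estimate, $\bar U$ = mean
within-imputation covariance, $B$ = between-imputation covariance,
$T = \bar U + (1 + 1/M)B$. Confidence intervals use the Barnard–Rubin
small-sample degrees of freedom with complete-data df
$\nu_{com} = n - p$ — the adjusted df is safe at small $M$, whereas the
classical large-sample df can exceed the information actually available.
The between-site variance is pooled by its mean only; no interval is
reported for it. $M = 1$ is permitted (then $B = 0$, with a warning).

## The simulation benchmark

The generator emulates an evenly split federation with one continuous
outcome and three covariates, each site carrying random intercepts:
$x_3 \sim N(0, 0.5^2)$; $x_2 \sim N(u_{i2} + 0.1x_3, 0.1^2)$,
$u_{i2} \sim N(0, 0.1^2)$; $x_1 \sim
\mathrm{Bern}(\mathrm{expit}(u_{i1} + 0.1x_2 + 0.1x_3))$,
$u_{i1} \sim N(0, 0.1^2)$; $y \sim N(-0.5 + 0.5x_1 + 0.5x_2 + 0.1x_3 +
u_{iy}, 0.5^2)$. The heterogeneity levels are the outcome
random-intercept **standard deviations** $\sigma_{uy} = 0.1$ (weak) and
$0.5$ (strong): under this reading the complete-data estimator's
between-replicate variability gap between the strong and weak settings
equals $(0.25-0.01)/L$ at every sample size, which is what the
complete-data analysis actually exhibits; reading the same figures as
variances overstates the gap roughly twofold.

Missingness is MAR: each targeted cell is masked with probability
$\mathrm{expit}(\alpha_0 + \sum \text{slope}\cdot\text{predictor})$ where
the predictors are fully observed quantities (scenario a: $x_2, x_3, y$
mask $x_1$; scenario b: $x_1, x_3, y$ mask $x_2$; scenario c: only
$x_3, y$ drive both masks, keeping the mechanism MAR when both targets
are incomplete). All slopes are 1.0 — the missingness-model coefficients
are a free design choice here, and the intercept calibration absorbs the
overall scale: $\alpha_0$ is bisected on a large pilot sample
(~$10^5$ rows sharing the cell's per-site size) until the expected rate
is within $10^{-3}$ of the 17.5% target, the midpoint of the intended
15–20% band.

Benchmark methods per replicate (paired on the same data and mask): CD
(fit on pre-mask data), CC (complete rows only), D3MI (one dPQL round per
fit), PQL (all fits iterated to convergence on pooled data — the
centralized reference; identical to D3MI for gaussian targets, where one
round already is the converged fit), and AVGM (imputation model without a
random intercept: per-site maximum-likelihood (G)LM fits on
observed-target rows, coefficients averaged with observed-count weights
$w_i = n_i^{obs}/N^{obs}$ and covariance $\sum w_i^2 \hat V_i$,
MVN draws, pooled residual-variance draw for gaussian targets, $v^* = 0$,
chaining otherwise identical). Sites whose local AVGM model cannot be
fitted are dropped with a warning; the method errors only if all fail.
Metrics over $R$ replicates of the full fixed-effect vector
$\beta_{true} = (-0.5, 0.5, 0.5, 0.1)$, $\|\beta_{true}\|_2 = \sqrt{0.76}$:

* Bias $= \|\bar{\hat\beta} - \beta_{true}\|_2/\|\beta_{true}\|_2$,
* SD $= \sqrt{\tfrac1R\sum \|\hat\beta_r - \bar{\hat\beta}\|_2^2}$,
* rMSE $= \sqrt{\tfrac1R\sum \|\hat\beta_r - \beta_{true}\|_2^2}$,

which satisfy $\mathrm{rMSE}^2 = \mathrm{SD}^2 + (\mathrm{Bias}\cdot
\|\beta_{true}\|_2)^2$ exactly — a standing regression test of the
definitions. Monte-Carlo standard errors of the metrics are estimated by
bootstrap over replicates. Default problem sizes: 200 replicates per
cell, $M = 5$, 10 chained-equation sweeps — a single cell runs in well
under two minutes on one CPU.

## What the generator does and does not emulate

It reproduces site-clustered covariates and outcome, MAR missingness
driven by observed variables, and both binary and continuous incomplete
covariates. It does **not** emulate unequal site sizes, missingness in
the outcome, not-at-random mechanisms, categorical variables with more
than two levels, or site-level covariate shift beyond random intercepts —
so passing benchmarks demonstrate correctness of the machinery and the
comparative behavior of the methods under these stylized conditions, not
performance on arbitrary real registries.

## Known limitations

* Binomial PQL carries the usual small-sample attenuation of fixed
  effects when random-intercept variance is large; at the benchmark's
  scales ($\sigma_v \le 0.5$) the effect is far below Monte-Carlo noise.
* The AVGM baseline here is a clean procedural rendering (local ML fits,
  weighted averaging, no random intercept). In our experiments its
  site-level imputation miscalibration is largely absorbed by the
  analysis GLMM's random intercept, so its between-replicate variability
  stays close to D3MI's under strong heterogeneity rather than exploding;
  published accounts of AVGM-style imputation report much larger
  instability, which evidently depends on implementation details of those
  tools (e.g. treatment of unstable local fits) that are not part of the
  procedural description implemented here.
* With very few sites ($L \le 3$) the $\sigma_v^{2*}$ draw is extremely
  heavy-tailed ($\chi^2$ with $L-1$ df in the denominator); this is
  inherent to the approximate-Bayesian scheme, not a numerical issue.
* Confidence intervals assume the gaussian analysis outcome; pooled
  binomial analyses reuse the same machinery but inherit PQL's
  approximation for their within-imputation covariances.
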