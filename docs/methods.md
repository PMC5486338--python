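# Methods

## Model

For child *i* with hemoglobin `y_i` (g/dL), categorical covariates
`x_i`, continuous covariates `u_i` and district `d_i`, the conditional
θ-quantile is

    Q_{y_i}(θ) = η_θi = x_i' β_θ + Σ_k f_θk(u_ki) + f_spat(d_i).

Estimating a conditional quantile is equivalent to minimising the check
(pinball) loss `ρ_θ(u) = u·(θ − 1{u<0})`, and — the device that makes
Bayesian computation possible — to maximising the likelihood of an
asymmetric Laplace (AL) distribution with fixed skewness θ:

    f(y | η, σ, θ) = θ(1−θ)/σ · exp(−ρ_θ((y − η)/σ)).

The AL admits a normal–exponential scale mixture: with
`ξ = (1−2θ)/(θ(1−θ))` and `ω² = 2/(θ(1−θ))`,

    y_i | z_i ~ N(η_i + ξ z_i, ω² σ z_i),   z_i ~ Exp(mean σ),

which turns every full conditional into a standard distribution. The
misspecification caveat applies as usual: the AL is a working
likelihood; its location parameter consistently targets the conditional
quantile, and we validate the posterior against the exact frequentist
LP solution rather than interpret σ substantively.

## Priors

- Fixed effects: diffuse N(0, 10⁶) per coefficient.
- Smooths: second-order random walk (RW2). On the sorted unique values
  of each covariate (all three are integer-valued: months of age,
  years, months of breastfeeding — treated as equispaced grids),
  `K = D₂'D₂` penalises squared second differences; rank m−2, null
  space = constants and linear trends.
- Spatial: intrinsic CAR (Besag), `K = diag(degree) − adjacency` from
  the district graph; rank n − (number of connected components).
- Variances: `τ² ~ IG(1, 0.005)` per block (a common structured
  additive default, weak on the variance scale of g/dL effects);
  `σ ~ IG(0.001, 0.001)`.

### Identifiability

RW2 and ICAR priors are improper. Each block is recentred to sum to
zero every iteration (per connected component for the spatial block)
with the removed mean absorbed into the intercept, so the predictor is
unchanged. We deliberately do **not** remove the linear trend from RW2
smooths: the models contain no separate parametric linear terms for the
smooth covariates, so the linear direction of each curve is identified
by the likelihood (different covariates are not collinear), and
detrending would discard the scientifically meaningful slope of, e.g.,
the child-age effect. `PenaltyBlock` records the full null-space
dimension (2 for RW2) alongside the constraint actually enforced.

## Sampler

Gibbs updates per iteration:

1. `z_i | ·` is generalized inverse Gaussian with index ½; its
   reciprocal is inverse Gaussian with mean `√(ψ/χ_i)` and shape ψ,
   where `χ_i = (y_i − η_i)²/(ω²σ)` and `ψ = 1/(2θ(1−θ)σ)` (χ is
   floored at 1e-12 for interpolated points).
2. β and each penalised block are multivariate normal draws with
   precision `A'WA + K/τ²` (dense Cholesky; block sizes are ≤ 60, and
   `A'WA` is diagonal for incidence blocks so assembly is O(n)).
3. `σ | · ~ IG(a + 3n/2, b + Σz_i + Σ(y−η−ξz)²/(2ω²z))`;
   `τ²_k | · ~ IG(a + rank/2, b + f'Kf/2)`.

Defaults: 12 000 iterations, 2 000 burn-in, thinning 5. A fit is fully
reproducible from its integer seed. Non-finite draws abort with a
diagnostic rather than silently continuing. The Gaussian-likelihood
variant (the mean-regression baseline) reuses the same skeleton with
conjugate normal/inverse-gamma updates so deviances are computed by the
same code path.

### Validation strategy

Three independent oracles guard the sampler: (i) the intercept-only
posterior must sit on the sample quantile; (ii) fixed-effects-only
posterior medians must agree with the exact LP vertex solution (HiGHS),
cross-checked in turn against statsmodels' interior-point quantile
regression; (iii) on generated data the full structured model must
recover the injected smooths, spatial field and fixed effects. The
LP-agreement check uses a balanced ten-covariate design (frequencies
25–75%): agreement there is 0.01–0.03 g/dL, far inside the 0.1
tolerance, which is what makes the check diagnostic. With very rare
covariates (e.g. a 1.8%-frequency indicator at θ = 0.15) both the LP
vertex and the posterior median have sampling error above 0.1 g/dL, so
point agreement at that tolerance is not a meaningful sampler check;
see Limitations.

## DIC

`D = −2 log L` (AL or Gaussian). `D̄` averages the deviance over stored
draws; the plug-in deviance evaluates at the posterior means of η and
of the scale; `pD = D̄ − D(mean)`; `DIC = D̄ + pD = D(mean) + 2 pD`.
The model ladder (1: Gaussian linear mean model with all covariates;
2: linear quantile; 3: + RW2 smooths; 4: + ICAR spatial; 5: smooths +
spatial) is ranked by DIC per quantile level, one table per θ, and the
argmin model is flagged. Comparing the Gaussian model's deviance with
the AL models' follows the published usage of the criterion; it is a
heuristic across likelihood families, which is one reason the selection
check below uses AL-generated data.

## Synthetic generator

The generator is the package's stand-in for the restricted survey and
defines the conditions under which everything is tested:

- Covariates: child age ~ uniform integers 0–59 months; mother's age at
  birth 15–49; breastfeeding 0–36 months; ten categorical covariates at
  survey-like marginal frequencies (e.g. male 50.6%, fever 20.7%,
  underweight 1.8%, wealth poor/middle/rich 47/20/33%); districts
  uniform over the graph.
- Fixed effects: the published posterior-mean estimates (male +0.1194,
  fever −0.3511, non-anemic mother +0.4427, rich +0.2259, … g/dL).
- Smooths (mean-centred, ≈ ±0.3 g/dL): child age increasing and concave
  (saturating exponential); mother's age negative before 20, positive
  20–30, dipping near 35 then rising (monotone-cubic through fixed
  knots); breastfeeding decreasing to a trough at 10 months then an
  inverse U peaking near 25.
- Spatial field: the Fiedler vector of the graph Laplacian scaled to
  sd 0.2 g/dL — smooth, clustered, sums to zero by construction. The
  default graph is a 5×6 rook lattice (30 districts).
- Noise (default "skew"): 0.9·N(0, 0.9601²) + 0.1·N(−2.5498, 1.9203²).
  The weights were fixed a priori; shift, scales and the intercept
  (11.0821) were calibrated once, by moment matching plus simulation of
  the complete generative model, so that the marginal Hb hits the three
  published summaries simultaneously: mean 11.25, sd 1.41 and 37% below
  11 g/dL. A left-skewed mixture is required — no Gaussian matches all
  three. Alternative noise families: plain Gaussian, and asymmetric
  Laplace at the design quantile (θ = 0.37 by default), for which the
  true conditional θ-quantile is exactly the linear predictor, making
  parameter recovery checks sharp.
- A separate fixture reproduces the published anemia-by-covariate 2×2
  counts exactly. Its variables are filled independently per margin
  (joint cell counts are not published), padded with per-variable
  missingness because the printed column totals disagree by ±1 across
  variables.

What the generator does *not* emulate: survey weights, stratification
and clustering; missingness mechanisms; the country's real district
adjacency; altitude adjustment of Hb (assumed done upstream); and any
dependence between covariates (they are drawn independently). Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated conditions, not robustness to complex-survey
artefacts.

## Problem sizes in the test suite

The checks are sized to be decisive yet quick: oracle agreement uses
n = 3000 with 6000 iterations; Model-5 recovery uses n = 4000 over ten
replicates (3000 iterations each); DIC selection refits all five models
on ten seeds at n = 2000; the generator calibration checks use the
survey's own n = 3248. The DIC-selection experiment generates data with
AL noise at θ = 0.37 so that the quantile models' likelihood family is
correctly specified — with the skew-mixture default the Gaussian mean
model occasionally edges out the quantile ladder on deviance, which is
a statement about cross-family DIC, not about model selection among the
structured quantile models.

## Numerical choices

- LP solver: HiGHS primal with split residuals; exact at a vertex. When
  more than p residuals are (numerically) zero the solution may be
  non-unique; this is logged. IRLS fallback: asymmetric weights with a
  1e-8 smoothing floor, 200 iterations max.
- Empirical quantiles are the inverted-CDF order statistic
  (`y_(⌈nθ⌉)`), the convention under which the LP vertex equals the
  sample quantile exactly when nθ is not an integer.
- Cross-tabulation percentages are rounded half-up to one decimal,
  matching printed-table display; the chi-square is classical Pearson
  without survey design corrections (screening on synthetic data uses
  the raw statistic; published p-values embed design effects we do not
  reproduce).
- Anemia categories use half-open intervals [0,7), [7,10), [10,11),
  [11,∞): the published bounds leave 0.1-wide gaps that we close from
  above, observationally equivalent for Hb recorded to 0.1 g/dL.
- Hemoglobin values are written to CSV rounded to 1e-6 g/dL, keeping
  file round-trips byte-stable.

## Limitations

- Quantile fits at different θ are independent; crossing of fitted
  quantile surfaces is neither prevented nor post-processed.
- For covariates observed in a few dozen children, posterior summaries
  at extreme quantile levels carry sampling error of ≈0.2 g/dL; point
  comparisons tighter than that (against any estimator) are not
  informative there.
- The unstructured iid child effect is supported but off by default in
  the ladder (the published model comparison omits it); fitting it to
  n children costs a dense n×n factorisation in the current
  implementation.
- DIC across likelihood families (Gaussian vs AL) inherits the usual
  caveats; within the AL ladder it behaves as expected (complexity
  penalised on null data, structure rewarded when present).
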