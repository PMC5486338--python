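# staqr — structured additive quantile regression for childhood hemoglobin

`staqr` implements a Bayesian structured additive quantile regression
pipeline for analysing determinants of childhood anemia from child-level
survey records (hemoglobin in g/dL, categorical and continuous
covariates, a district label) together with a district adjacency graph.
It is aimed at epidemiologists and biostatisticians who want to model
the *lower tail* of the hemoglobin distribution — where anemia lives —
rather than its mean, and to map residual spatial risk at district
level.

Because survey micro-data of this kind is access-restricted, the package
ships a first-class synthetic generator that emulates the survey
structure (left-skewed Hb centred near 11.25 g/dL, sd ≈ 1.41, ≈37% of
children below the 11 g/dL anemia cut-off, nonlinear age/breastfeeding
effects, spatially clustered district effects) with known ground truth,
so every stage is testable end to end.

## The model

For a fixed quantile level θ ∈ (0, 1), the conditional θ-quantile of
child *i*'s hemoglobin is modelled as

```
Q_{Y_i}(θ | x_i, u_i) = η_θi = x_i'β_θ + Σ_k f_θk(u_ki) + f_θ(spat)(d_i)
```

with categorical fixed effects β_θ (reference-category coding), smooth
functions f_θk of child age, mother's age at birth and breastfeeding
duration under second-order random-walk (RW2) priors, and a district
effect under an intrinsic CAR (Besag) prior built from the adjacency
graph. Fitting minimises the check loss ρ_θ(u) = u(θ − 1{u<0}),
equivalently maximises an asymmetric Laplace (AL) likelihood; the
posterior is explored with the normal–exponential scale-mixture Gibbs
sampler, whose full conditionals are all closed form. A ladder of five
models (Gaussian linear mean model; linear, additive, spatial, and
structured spatial additive quantile regression) is compared by DIC.
Quantile levels of interest map to anemia-category prevalences
(θ = 0.15 moderate, 0.21 mild, 0.37 any anemia).

The frequentist linear-programming quantile fit (exact vertex solution)
is included and doubles as the independent oracle for the sampler.

## Worked example

```python
from staqr import (SimConfig, generate_dataset, make_lattice_graph,
                   CovariateRoles, eda_summary, prevalence_to_theta,
                   fit_ladder, compare_models, effects_table)
from staqr.synthetic import CATEGORICAL_VARS

data, truth = generate_dataset(SimConfig(n_children=3248, seed=1))
graph = make_lattice_graph(5, 6)          # 30-district rook lattice
roles = CovariateRoles(categorical=CATEGORICAL_VARS)

tabs, screened = eda_summary(data)        # chi-square screen at p < 0.2
theta = prevalence_to_theta(data.hb)      # 0.376 on this draw

fits = fit_ladder(data, graph, roles, theta=0.37, levels=(2, 5),
                  iters=4000, burnin=1000, thin=3, seed=0)
print(compare_models(fits).round(2))
print(effects_table({0.37: fits[5]})
      .loc[["sex=male", "fever=yes", "mother_anemia=not_anemic"]].round(3))
```

prints

```
           model_2   model_5
DIC       11523.37  11292.05
pD           12.54     55.66
D         11498.30  11180.73
selected      0.00      1.00

theta                      0.37
stat                       mean     sd   q2.5  q97.5 significant
sex=male                  0.111  0.041  0.034  0.190        True
fever=yes                -0.470  0.048 -0.561 -0.375        True
mother_anemia=not_anemic  0.463  0.055  0.355  0.568        True
```

The structured spatial additive model (model 5) wins the DIC comparison
(11292 vs 11523; pD is its effective parameter count). The fixed-effect
rows are on the hemoglobin scale: being male raises the conditional
0.37-quantile of Hb by ≈0.11 g/dL (less anemia), a recent fever lowers
it by ≈0.47 g/dL, and having a non-anemic mother raises it by
≈0.46 g/dL — each 95% credible interval excludes zero, and each sign
matches the effect injected by the generator. `spatial_table(fits[5])`
adds per-district posterior effects with a lower-/higher-risk coding,
and `smooth_curves(fits[5], "child_age")` returns the posterior smooth
with credible bands.

The same pipeline is scriptable from a shell:

```sh
staqr simulate --n 3248 --districts 30 --seed 1 --out sim/
staqr eda     --data sim/data.csv --out tables/
staqr compare --data sim/data.csv --graph sim/graph.gra --theta 0.37 --out cmp/
staqr report  --data sim/data.csv --graph sim/graph.gra \
              --theta 0.15,0.21,0.37,0.5 --out report/
```

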