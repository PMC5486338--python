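"""Design assembly, Gibbs sampler correctness and DIC."""

import numpy as np
import pandas as pd
import pytest

from staqr import (ChildDataset, DicComponents, ModelSpec, SimConfig,
                   build_predictor, compute_dic, dic_identity, fit_linear_qr,
                   generate_dataset, gibbs_fit)
from staqr.gibbs import FitResult


@pytest.fixture(scope="module")
def sex_only_data():
    df = pd.DataFrame({"hb": [10.0, 11.0, 12.0, 13.0],
                       "sex": ["female", "male", "male", "female"]})
    return ChildDataset(df, district_col=None, categorical=("sex",),
                        references={"sex": "female"})


def test_dummy_coding_reference_category(sex_only_data):
    spec = ModelSpec(theta=0.5, fixed_terms=("sex",))
    pred = build_predictor(spec, sex_only_data)
    assert pred.colnames == ["Intercept", "sex=male"]
    assert np.array_equal(pred.X[:, 1], [0.0, 1.0, 1.0, 0.0])
    assert pred.blocks == []


def test_incidence_matrix_one_per_row(default_data, lattice30):
    data, _ = default_data
    spec = ModelSpec(theta=0.37, smooth_terms=("child_age",),
                     spatial_term="district")
    pred = build_predictor(spec, data, lattice30)
    smooth = pred.blocks[0]
    assert np.array_equal(smooth.grid, np.unique(data.df["child_age"]))
    assert np.array_equal(smooth.grid[smooth.idx],
                          data.df["child_age"].to_numpy(dtype=float))
    spat = pred.blocks[1]
    counts = np.bincount(spat.idx, minlength=30)
    assert counts.sum() == data.n


def test_unseen_district_rejected(lattice30):
    df = pd.DataFrame({"hb": [10.0, 11.0], "district": ["d01", "zzz"]})
    data = ChildDataset(df)
    spec = ModelSpec(theta=0.37, spatial_term="district")
    with pytest.raises(ValueError, match="zzz"):
        build_predictor(spec, data, lattice30)


def test_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(theta=None, likelihood="asymmetric-laplace")
    with pytest.raises(ValueError):
        ModelSpec(theta=0.5, likelihood="gaussian")
    with pytest.raises(ValueError):
        ModelSpec(theta=1.2)


@pytest.fixture(scope="module")
def intercept_fit(simple_dataset):
    spec = ModelSpec(theta=0.5)
    return gibbs_fit(spec, simple_dataset, iters=3000, burnin=500, thin=2,
                     seed=1)


def test_intercept_model_targets_sample_median(simple_dataset, intercept_fit):
    med = np.median(simple_dataset.hb)
    assert np.median(intercept_fit.beta[:, 0]) == pytest.approx(med,
                                                                abs=0.08)


def test_quantile_calibration(simple_dataset):
    """Proportion of observations below the fitted theta-intercept is
    within 0.02 of theta (n=5000)."""
    fit = gibbs_fit(ModelSpec(theta=0.37), simple_dataset, iters=3000,
                    burnin=500, thin=2, seed=3)
    b0 = fit.beta[:, 0].mean()
    assert np.mean(simple_dataset.hb < b0) == pytest.approx(0.37, abs=0.02)


def test_chain_seed_determinism(simple_dataset):
    spec = ModelSpec(theta=0.37)
    a = gibbs_fit(spec, simple_dataset, iters=400, burnin=100, thin=1, seed=9)
    b = gibbs_fit(spec, simple_dataset, iters=400, burnin=100, thin=1, seed=9)
    assert np.array_equal(a.beta, b.beta)
    assert np.array_equal(a.scale, b.scale)
    assert np.array_equal(a.deviance, b.deviance)
    c = gibbs_fit(spec, simple_dataset, iters=400, burnin=100, thin=1, seed=10)
    assert not np.array_equal(a.beta, c.beta)


def test_positivity_and_pd(intercept_fit, simple_dataset):
    assert np.all(intercept_fit.scale > 0)
    dic = compute_dic(intercept_fit, simple_dataset)
    assert dic.pD > 0
    assert dic.DIC == pytest.approx(dic.Dbar + dic.pD)
    assert dic.pD == pytest.approx(dic.Dbar - dic.D_at_mean)


@pytest.fixture(scope="module")
def model5_small():
    """Small structured fit shared across constraint/DIC checks."""
    from staqr import CovariateRoles, build_model, make_lattice_graph
    from staqr.synthetic import CATEGORICAL_VARS, _lattice_dims
    data, truth = generate_dataset(
        SimConfig(n_children=2000, seed=21, noise="asymmetric-laplace"))
    graph = make_lattice_graph(*_lattice_dims(30))
    roles = CovariateRoles(categorical=CATEGORICAL_VARS)
    fit = gibbs_fit(build_model(5, 0.37, roles), data, graph,
                    iters=1500, burnin=300, thin=3, seed=4)
    return data, truth, fit


def test_constraints_hold_for_every_draw(model5_small):
    _, _, fit = model5_small
    for name, draws in fit.smooths.items():
        sums = draws.sum(axis=1)
        assert np.max(np.abs(sums)) < 1e-8, name


def test_structured_fit_dic_components(model5_small):
    data, _, fit = model5_small
    assert fit.dic is not None
    assert fit.dic.pD > 0
    # more complexity than the 12 fixed effects + scale alone
    assert fit.dic.pD > 14


def test_gibbs_matches_lp_small(model5_small):
    """Fixed-effects-only posterior medians sit on the LP solution."""
    data, _, _ = model5_small
    from staqr.synthetic import CATEGORICAL_VARS
    spec = ModelSpec(theta=0.37, fixed_terms=CATEGORICAL_VARS)
    fit = gibbs_fit(spec, data, iters=2500, burnin=500, thin=2, seed=6)
    pred = build_predictor(spec, data)
    lp = fit_linear_qr(pred.X, data.hb, 0.37)
    assert np.max(np.abs(np.median(fit.beta, axis=0) - lp)) < 0.15


def test_gaussian_likelihood_fit(default_data):
    data, _ = default_data
    spec = ModelSpec(theta=None, likelihood="gaussian",
                     fixed_terms=("sex", "fever"))
    fit = gibbs_fit(spec, data, iters=1000, burnin=200, thin=2, seed=2)
    # posterior mean close to OLS
    pred = build_predictor(spec, data)
    ols = np.linalg.lstsq(pred.X, data.hb, rcond=None)[0]
    assert np.allclose(fit.beta.mean(axis=0), ols, atol=0.05)
    assert fit.dic.pD == pytest.approx(4.0, abs=1.5)  # 3 betas + variance


def test_compute_dic_needs_draws(simple_dataset, intercept_fit):
    short = FitResult(spec=intercept_fit.spec, colnames=["Intercept"],
                      beta=intercept_fit.beta[:10],
                      smooths={}, grids={}, tau2={},
                      scale=intercept_fit.scale[:10],
                      deviance=intercept_fit.deviance[:10],
                      eta_mean=intercept_fit.eta_mean,
                      meta=intercept_fit.meta)
    with pytest.raises(ValueError):
        compute_dic(short, simple_dataset)


def test_degenerate_chain_has_zero_pd(simple_dataset, intercept_fit):
    """All draws identical: Dbar equals the plug-in deviance, pD = 0."""
    n = simple_dataset.n
    const_eta = np.full(n, float(np.median(simple_dataset.hb)))
    from staqr.gibbs import _al_deviance
    dev = _al_deviance(simple_dataset.hb, const_eta, 1.0, 0.5)
    frozen = FitResult(spec=ModelSpec(theta=0.5), colnames=["Intercept"],
                       beta=np.zeros((100, 1)), smooths={}, grids={},
                       tau2={}, scale=np.ones(100),
                       deviance=np.full(100, dev), eta_mean=const_eta,
                       meta={})
    dic = compute_dic(frozen, simple_dataset)
    assert dic.pD == pytest.approx(0.0, abs=1e-9)
    assert dic.DIC == pytest.approx(dic.Dbar)


def test_dic_identity_printed_style_inputs():
    assert dic_identity(0.0, 0.0) == 0.0
    assert dic_identity(10660.2, 23.74) == pytest.approx(10707.68)
    assert dic_identity(10931.0, 32.98) == pytest.approx(10996.96)


def test_iters_must_exceed_burnin(simple_dataset):
    with pytest.raises(ValueError):
        gibbs_fit(ModelSpec(theta=0.5), simple_dataset, iters=100,
                  burnin=100, thin=1, seed=0)
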