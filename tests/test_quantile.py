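"""Check-loss machinery, LP quantile fits and the AL density."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from staqr import (ALParams, al_logpdf, check_loss, fit_linear_qr,
                   mixture_constants, sample_al, total_loss)


@pytest.mark.parametrize("u, theta, expected", [
    (1.0, 0.37, 0.37),
    (-1.0, 0.37, 0.63),
    (0.0, 0.9, 0.0),
    (2.5, 0.15, 0.375),
])
def test_check_loss_piecewise(u, theta, expected):
    assert check_loss(u, theta) == pytest.approx(expected)


@given(st.floats(-1e6, 1e6), st.floats(0.01, 0.99))
def test_check_loss_reflection_identity(u, theta):
    """rho_theta(u) + rho_theta(-u) == |u|, equivalently
    rho_theta(u) + rho_{1-theta}(u) == |u|."""
    assert check_loss(u, theta) + check_loss(-u, theta) == \
        pytest.approx(abs(u), abs=1e-9, rel=1e-9)
    assert check_loss(u, theta) + check_loss(u, 1.0 - theta) == \
        pytest.approx(abs(u), abs=1e-9, rel=1e-9)


def test_check_loss_rejects_bad_theta():
    with pytest.raises(ValueError):
        check_loss(1.0, 1.0)


def test_total_loss_examples():
    y = np.array([0.0, 1.0])
    assert total_loss(y, y, 0.3) == 0.0
    assert total_loss(y, y[::-1], 0.5) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        total_loss(y, np.zeros(3), 0.5)


def test_median_minimises_constant_total_loss():
    """Grid search over constants: the median minimises at theta=0.5."""
    rng = np.random.default_rng(4)
    y = rng.exponential(2.0, 200)
    med_loss = total_loss(y, np.full_like(y, np.median(y)), 0.5)
    grid = np.linspace(y.min(), y.max(), 400)
    losses = [total_loss(y, np.full_like(y, c), 0.5) for c in grid]
    assert med_loss <= min(losses) + 1e-9


@pytest.mark.parametrize("theta", [0.15, 0.21, 0.37, 0.5])
def test_lp_intercept_is_empirical_quantile(theta):
    rng = np.random.default_rng(1)
    y = rng.normal(0.0, 2.0, 101)  # n*theta non-integer: unique minimiser
    beta = fit_linear_qr(np.ones((101, 1)), y, theta)
    assert beta[0] == pytest.approx(
        np.quantile(y, theta, method="inverted_cdf"), abs=1e-9)


def test_lp_slope_recovery_under_al_noise():
    rng = np.random.default_rng(7)
    x = rng.uniform(0.0, 10.0, 2000)
    y = 2.0 * x + sample_al(rng, 2000, 0.0, 1.0, 0.37)
    X = np.column_stack([np.ones(2000), x])
    beta = fit_linear_qr(X, y, 0.37)
    assert beta[1] == pytest.approx(2.0, abs=0.1)


def test_lp_invariant_to_duplicated_rows():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(60), rng.normal(size=60)])
    y = rng.normal(size=60)
    b1 = fit_linear_qr(X, y, 0.37)
    b2 = fit_linear_qr(np.vstack([X, X]), np.concatenate([y, y]), 0.37)
    assert np.allclose(b1, b2, atol=1e-8)


def test_lp_matches_statsmodels():
    """Independent frequentist oracle: statsmodels interior-point QR."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(500), rng.normal(size=(500, 2))])
    y = X @ np.array([1.0, -0.5, 2.0]) + rng.standard_t(5, 500)
    for theta in (0.21, 0.5):
        ours = fit_linear_qr(X, y, theta)
        ref = sm.QuantReg(y, X).fit(q=theta).params
        assert np.allclose(ours, ref, atol=1e-4)


def test_irls_agrees_with_lp():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(400), rng.normal(size=400)])
    y = X @ np.array([0.5, 1.5]) + rng.normal(size=400)
    assert np.allclose(fit_linear_qr(X, y, 0.37, method="irls"),
                       fit_linear_qr(X, y, 0.37), atol=1e-4)


def test_lp_input_validation():
    X = np.ones((5, 1))
    with pytest.raises(ValueError):
        fit_linear_qr(np.hstack([X, X]), np.zeros(5), 0.5)  # rank deficient
    with pytest.raises(ValueError):
        fit_linear_qr(np.ones((2, 3)), np.zeros(2), 0.5)  # n <= p


def test_al_params_mixture_constants():
    p = ALParams(mu=0.0, sigma=1.0, theta=0.5)
    assert p.xi == pytest.approx(0.0)
    assert p.omega2 == pytest.approx(8.0)
    assert mixture_constants(0.25) == pytest.approx((8.0 / 3.0, 32.0 / 3.0))
    with pytest.raises(ValueError):
        ALParams(mu=0.0, sigma=0.0, theta=0.5)


def test_al_logpdf_at_mode_and_normalisation():
    p = ALParams(mu=2.0, sigma=1.0, theta=0.5)
    assert al_logpdf(2.0, p) == pytest.approx(np.log(0.25))
    pa = ALParams(mu=-1.0, sigma=0.7, theta=0.21)
    # integration range scaled to the slow exp(-theta |u| / sigma) tail
    span = 60.0 * pa.sigma / min(pa.theta, 1 - pa.theta)
    lower = quad(lambda t: np.exp(al_logpdf(t, pa)), -1 - span, -1.0,
                 limit=200)[0]
    upper = quad(lambda t: np.exp(al_logpdf(t, pa)), -1.0, -1 + span,
                 limit=200)[0]
    assert lower + upper == pytest.approx(1.0, abs=1e-6)


def test_al_sampler_quantile_property():
    """The theta-quantile of AL(mu, sigma, theta) is mu."""
    rng = np.random.default_rng(6)
    for theta in (0.15, 0.37):
        draws = sample_al(rng, 200_000, mu=1.5, sigma=0.8, theta=theta)
        assert np.mean(draws <= 1.5) == pytest.approx(theta, abs=0.005)
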