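import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from superstat.distributions import (
    BETA_FAMILIES,
    Chi2MixtureParams,
    Chi2Params,
    DegenerateInputError,
    InvChi2Params,
    LogNormalParams,
    QGaussianParams,
    beta_pdf,
    beta_rvs,
    chi2_from_qgaussian,
    chi2_mixture_pdf,
    compare_fits,
    fit_beta_family,
    fit_chi2_mixture,
    fit_qgaussian,
    kde_pdf,
    qgaussian_from_chi2,
    qgaussian_pdf,
    qgaussian_rvs,
)


# ---------------------------------------------------------------- densities

@pytest.mark.parametrize(
    "family,params",
    [
        ("chi2", Chi2Params(n=4, beta0=2.0)),
        ("chi2", Chi2Params(n=1.3, beta0=0.5)),
        ("inv_chi2", InvChi2Params(n=6, beta0=1.5)),
        ("lognormal", LogNormalParams(mu_ln=0.3, sigma_ln=0.8)),
        ("chi2_mixture", Chi2MixtureParams(W=0.3, n1=1, n2=20, beta0=2.0)),
    ],
)
def test_beta_densities_normalized(family, params):
    total, _ = quad(lambda b: float(beta_pdf(family, params, b)), 0, np.inf, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_chi2_mean_is_beta0():
    params = Chi2Params(n=4, beta0=2.0)
    mean, _ = quad(
        lambda b: b * float(beta_pdf("chi2", params, b)), 0, np.inf, limit=200
    )
    assert mean == pytest.approx(2.0, rel=1e-6)


def test_chi2_concentrates_for_large_n():
    params = Chi2Params(n=1e4, beta0=2.0)
    mass, _ = quad(
        lambda b: float(beta_pdf("chi2", params, b)), 1.9, 2.1, limit=200
    )
    assert mass > 0.99


def test_beta_pdf_rejects_nonpositive():
    with pytest.raises(ValueError):
        beta_pdf("chi2", Chi2Params(n=4, beta0=2.0), -1.0)


# ---------------------------------------------------------------- q-Gaussian

def test_qgaussian_gaussian_limit():
    p = QGaussianParams(q=1.000001, b=0.5, mu=0.0)
    gauss_at_zero = 1.0 / np.sqrt(2 * np.pi * 1.0)  # variance 1/(2b) = 1
    assert float(qgaussian_pdf(0.0, p)) == pytest.approx(gauss_at_zero, abs=1e-4)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    q=st.floats(1.01, 2.7),
    b=st.floats(0.1, 10.0),
    mu=st.floats(-5, 5),
    d=st.floats(0.01, 10.0),
)
def test_qgaussian_symmetric_about_mu(q, b, mu, d):
    p = QGaussianParams(q=q, b=b, mu=mu)
    assert float(qgaussian_pdf(mu + d, p)) == pytest.approx(
        float(qgaussian_pdf(mu - d, p)), rel=1e-12
    )


def test_qgaussian_normalized():
    p = QGaussianParams(q=1.5, b=1.0, mu=0.0)
    total, _ = quad(lambda x: float(qgaussian_pdf(x, p)), -np.inf, np.inf, limit=400)
    assert total == pytest.approx(1.0, abs=1e-8)


def test_qgaussian_domain_error():
    with pytest.raises(ValueError):
        qgaussian_pdf(0.0, QGaussianParams(q=3.2, b=1.0, mu=0.0))
    with pytest.raises(ValueError):
        qgaussian_pdf(0.0, QGaussianParams(q=0.5, b=1.0, mu=0.0))


def test_qgaussian_sampler_matches_pdf(rng):
    """Empirical CDF of the sampler vs the quadrature CDF of the density."""
    p = QGaussianParams(q=1.4, b=2.0, mu=0.5)
    draws = np.sort(qgaussian_rvs(p, 100_000, rng))
    grid = draws[:: len(draws) // 400]
    pdf_grid = np.linspace(grid[0] - 5, grid[-1] + 5, 4001)
    pdf = qgaussian_pdf(pdf_grid, p)
    cdf = np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(pdf_grid))
    cdf_at = np.interp(grid, pdf_grid[1:], cdf)
    emp = np.searchsorted(draws, grid, side="right") / len(draws)
    assert np.max(np.abs(emp - cdf_at)) < 0.01


def test_chi2_qgaussian_correspondence_roundtrip():
    p = qgaussian_from_chi2(n=4, beta0=2.0)
    back = chi2_from_qgaussian(p)
    assert back.n == pytest.approx(4.0)
    assert back.beta0 == pytest.approx(2.0)


# ---------------------------------------------------------------- mixture pdf

def test_mixture_reduces_to_single_component():
    single = Chi2Params(n=3, beta0=2.0)
    mix_w1 = Chi2MixtureParams(W=1.0, n1=3, n2=17, beta0=2.0)
    mix_eq = Chi2MixtureParams(W=0.5, n1=3, n2=3, beta0=2.0)
    b = np.linspace(0.05, 10, 200)
    np.testing.assert_allclose(
        chi2_mixture_pdf(b, mix_w1), beta_pdf("chi2", single, b), rtol=1e-12
    )
    np.testing.assert_allclose(
        chi2_mixture_pdf(b, mix_eq), beta_pdf("chi2", single, b), rtol=1e-12
    )


def test_mixture_bimodal_density():
    params = Chi2MixtureParams(W=0.3, n1=1, n2=30, beta0=2.0)
    b = np.linspace(1e-3, 10, 5000)
    p = chi2_mixture_pdf(b, params)
    # boundary-adjacent peak (density decreasing from the left edge) and an
    # interior local maximum
    assert p[0] > p[100]
    interior = (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])
    peaks = b[1:-1][interior]
    assert any(peak > 1.0 for peak in peaks)


# ---------------------------------------------------------------- fitters

def test_lognormal_mle_recovery(rng):
    draws = beta_rvs("lognormal", LogNormalParams(0.0, 0.5), 10_000, rng)
    res = fit_beta_family(draws, "lognormal")
    assert 0.48 <= res.params.sigma_ln <= 0.52
    assert res.aic == pytest.approx(2 * 2 - 2 * res.loglik)


def test_chi2_mle_recovery(rng):
    draws = beta_rvs("chi2", Chi2Params(4, 2.0), 10_000, rng)
    res = fit_beta_family(draws, "chi2")
    assert 1.9 <= res.params.beta0 <= 2.1


def test_invchi2_mle_recovery(rng):
    draws = beta_rvs("inv_chi2", InvChi2Params(6, 1.5), 10_000, rng)
    res = fit_beta_family(draws, "inv_chi2")
    assert res.params.n == pytest.approx(6.0, rel=0.1)
    assert res.params.beta0 == pytest.approx(1.5, rel=0.1)


def test_lognormal_degenerate_input():
    with pytest.raises(DegenerateInputError):
        fit_beta_family(np.full(50, 2.0), "lognormal")


def test_qgaussian_mle_recovery(rng):
    draws = qgaussian_rvs(QGaussianParams(1.3, 1.0, 0.0), 30_000, rng)
    res = fit_qgaussian(draws)
    assert res.converged
    assert res.params.q == pytest.approx(1.3, abs=0.08)
    assert res.aic == pytest.approx(2 * 3 - 2 * res.loglik)


def test_qgaussian_gaussian_data_gives_q_near_one(rng):
    res = fit_qgaussian(rng.standard_normal(50_000))
    assert 1.0 <= res.params.q <= 1.05


def test_qgaussian_needs_samples():
    with pytest.raises(ValueError):
        fit_qgaussian(np.arange(50.0))


def test_mixture_loglik_nesting(rng):
    """The two-component fit can never be worse than the single χ² fit."""
    draws = beta_rvs("chi2", Chi2Params(6, 2.0), 500, rng)
    single = fit_beta_family(draws, "chi2")
    mixture = fit_chi2_mixture(draws)
    assert mixture.loglik >= single.loglik - 1e-6
    # ...but AIC penalizes the two unused parameters
    assert single.aic < mixture.aic


def test_mixture_em_recovery_small(rng):
    truth = Chi2MixtureParams(W=0.3, n1=1.0, n2=20.0, beta0=2.0)
    draws = beta_rvs("chi2_mixture", truth, 3000, rng)
    res = fit_chi2_mixture(draws, seed=1)
    assert res.converged
    assert res.params.n1 <= res.params.n2  # label convention
    assert res.params.W == pytest.approx(0.3, abs=0.1)
    assert res.params.beta0 == pytest.approx(2.0, rel=0.2)


def test_compare_fits_identifies_lognormal(rng):
    wins = 0
    for seed in range(20):
        g = np.random.default_rng(1000 + seed)
        draws = beta_rvs("lognormal", LogNormalParams(0.0, 1.0), 500, g)
        ranked = compare_fits(draws, seed=seed)
        wins += ranked[0].family == "lognormal"
    assert wins >= 16


def test_compare_fits_single_family():
    ranked = compare_fits(np.abs(np.random.default_rng(0).standard_normal(100)) + 0.1,
                          families=("chi2",))
    assert len(ranked) == 1 and ranked[0].family == "chi2"


def test_compare_fits_failed_family_flagged_and_ranked_last(rng):
    draws = np.full(60, 3.0)  # zero log-variance: degenerate for log-normal
    ranked = compare_fits(draws, families=("lognormal", "chi2"))
    lognorm = next(r for r in ranked if r.family == "lognormal")
    assert not lognorm.converged
    assert lognorm.aic == np.inf
    # no converged result may rank below a failed one
    flags = [r.converged for r in ranked]
    assert flags == sorted(flags, reverse=True)


# ---------------------------------------------------------------- KDE

def test_kde_matches_gaussian_density(rng):
    x = rng.standard_normal(10_000)
    grid = np.linspace(-6, 6, 501)
    dens = kde_pdf(x, grid)
    assert dens[250] == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.1)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)


def test_kde_degenerate_input():
    with pytest.raises(DegenerateInputError):
        kde_pdf(np.full(100, 1.0), np.linspace(0, 2, 10))
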