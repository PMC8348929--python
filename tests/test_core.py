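import numpy as np
import pytest

from superstat.core import (
    SuperstatAnalyzer,
    TimescaleEstimate,
    UndefinedResultError,
    average_kurtosis,
    check_separation,
    extract_betas,
    kurtosis_curve,
    long_timescale,
    short_timescale,
    short_timescale_filter_corrected,
)
from superstat.detrend import SeasonalDetrender


def brute_force_average_kurtosis(u, window, stride):
    """Independent four-line oracle for the windowed moment kurtosis."""
    kappas = []
    for start in range(0, len(u) - window + 1, stride):
        w = u[start : start + window]
        d = w - w.mean()
        m2, m4 = np.mean(d**2), np.mean(d**4)
        if m2 > 0:
            kappas.append(m4 / m2**2)
    return float(np.mean(kappas))


def test_average_kurtosis_matches_brute_force(rng):
    u = rng.standard_normal(5000) * (1 + 0.5 * np.sin(np.arange(5000) / 300))
    for window, stride in [(100, 10), (64, 64), (333, 17)]:
        ours = average_kurtosis(u, window, stride)
        oracle = brute_force_average_kurtosis(u, window, stride)
        assert ours == pytest.approx(oracle, rel=1e-10)


def test_gaussian_kurtosis_near_three(rng):
    u = rng.standard_normal(40_000)
    assert average_kurtosis(u, 2000, 500) == pytest.approx(3.0, abs=0.15)


def test_constant_series_undefined():
    with pytest.raises(UndefinedResultError):
        average_kurtosis(np.ones(1000), 100, 10)


def test_variance_mixture_is_leptokurtic(rng):
    u = np.r_[rng.standard_normal(5000), 5.0 * rng.standard_normal(5000)]
    k = average_kurtosis(u, window=len(u), stride=1)
    assert k > 3.0


def test_kurtosis_curve_wrapper_identity(rng):
    u = rng.standard_normal(4000)
    curve = kurtosis_curve(u, window_grid_hours=[4.0], step_minutes=15.0, stride=5)
    assert len(curve.kappa_bar) == 1
    assert curve.kappa_bar[0] == pytest.approx(average_kurtosis(u, 16, 5), rel=1e-12)


def test_kurtosis_curve_rises_for_switching_variance(rng):
    # β alternates between regimes on a scale of 400 samples
    blocks = [rng.standard_normal(400) * (0.3 if i % 2 else 3.0) for i in range(40)]
    u = np.concatenate(blocks)
    curve = kurtosis_curve(
        u, window_grid_hours=[2.0, 400 * 0.25], step_minutes=15.0
    )
    assert curve.kappa_bar[-1] > curve.kappa_bar[0]


def test_long_timescale_linear_interpolation():
    from superstat.core import KurtosisCurve

    curve = KurtosisCurve(
        window_hours=np.array([10.0, 20.0]),
        kappa_bar=np.array([2.5, 3.5]),
        stride_samples=np.array([1, 1]),
        n_windows=np.array([10, 10]),
    )
    assert long_timescale(curve) == pytest.approx(15.0)


def test_long_timescale_undefined_below_target():
    from superstat.core import KurtosisCurve

    curve = KurtosisCurve(
        window_hours=np.array([10.0, 20.0, 40.0]),
        kappa_bar=np.array([2.0, 2.5, 2.8]),
        stride_samples=np.ones(3, int),
        n_windows=np.ones(3, int),
    )
    assert long_timescale(curve) is None


def test_short_timescale_ar1(rng):
    # AR(1) with phi=0.9: ACF phi^k crosses 1/e at k = 1/ln(1/phi) = 9.49
    phi = 0.9
    n = 200_000
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    tau, limited, tau_fit = short_timescale(x, step_minutes=15.0)
    expected = -0.25 / np.log(phi)  # hours
    assert not limited
    assert tau == pytest.approx(expected, rel=0.15)
    assert tau_fit is not None


def test_short_timescale_white_noise_resolution_limited(rng):
    tau, limited, _ = short_timescale(rng.standard_normal(10_000), step_minutes=15.0)
    assert limited
    assert tau == pytest.approx(0.25)


def test_filter_corrected_tau_removes_detrending_bias(rng):
    # OU with tau = 1 h at 15-min sampling, detrended by a 6-h moving average
    phi = np.exp(-0.25)
    n = 100_000
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + np.sqrt(1 - phi**2) * eps[i]
    det = SeasonalDetrender(f_hours=6, step_minutes=15.0).fit(x)
    u = det.fluctuations_[np.isfinite(det.fluctuations_)]
    naive, _, _ = short_timescale(u, 15.0)
    corrected = short_timescale_filter_corrected(u, det.filter_weights_, 15.0)
    assert corrected == pytest.approx(1.0, abs=0.15)
    assert abs(corrected - 1.0) < abs(naive - 1.0)


def test_extract_betas_floor_rule(rng):
    w = 64
    u = rng.standard_normal(10 * w + w // 2)
    bs = extract_betas(u, T_hours=16.0, step_minutes=15.0)
    assert bs.samples_per_window == w
    assert len(bs) == 10


def test_extract_betas_concentrates_on_true_inverse_variance(rng):
    u = 2.0 * rng.standard_normal(50 * 1000)  # N(0, 4) -> beta = 0.25
    bs = extract_betas(u, T_hours=250.0, step_minutes=15.0)
    assert len(bs) == 50
    assert np.mean(bs.betas) == pytest.approx(0.25, abs=0.02)


def test_extract_betas_bimodal_regimes(rng):
    w = 96
    sigmas = np.where(np.arange(60) % 2 == 0, 1.0, 0.1)
    u = np.concatenate([s * rng.standard_normal(w) for s in sigmas])
    bs = extract_betas(u, T_hours=24.0, step_minutes=15.0)
    low = bs.betas[bs.betas < 10]
    high = bs.betas[bs.betas >= 10]
    assert len(low) == 30 and len(high) == 30
    assert np.median(low) == pytest.approx(1.0, rel=0.5)
    assert np.median(high) == pytest.approx(100.0, rel=0.5)


def test_extract_betas_needs_enough_windows(rng):
    with pytest.raises(Exception, match="windows"):
        extract_betas(rng.standard_normal(100), T_hours=16.0, step_minutes=15.0)


def test_check_separation_arithmetic():
    est = TimescaleEstimate(T_hours=16.0, tau_hours=1.0)
    out = check_separation(est)
    assert out["applicable"] and out["passed"]
    assert out["ratio"] == pytest.approx(0.0625)

    est = TimescaleEstimate(T_hours=16.0, tau_hours=8.0)
    out = check_separation(est)
    assert out["applicable"] and not out["passed"]
    assert out["ratio"] == pytest.approx(0.5)

    est = TimescaleEstimate(T_hours=None, tau_hours=1.0)
    assert check_separation(est)["applicable"] is False


def test_analyzer_composes_stage_functions(synthetic_60d):
    _, series, _ = synthetic_60d
    det = SeasonalDetrender(f_hours=6, step_minutes=15.0).fit(series.values)
    u = det.fluctuations_[np.isfinite(det.fluctuations_)]
    grid = np.geomspace(2, 200, 20)
    analyzer = SuperstatAnalyzer(window_grid_hours=grid, step_minutes=15.0).fit(u)
    curve = kurtosis_curve(u, grid, 15.0)
    np.testing.assert_allclose(analyzer.curve_.kappa_bar, curve.kappa_bar)
    assert analyzer.T_hours_ == long_timescale(curve)
    if analyzer.T_hours_ is not None:
        assert analyzer.betas_ is not None
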