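"""Nonlinear decay fitting: exact limits, oracles, fit statistics."""

import numpy as np
import pytest

from braotrial import (
    fit_single_phase_decay,
    goodness_of_fit,
    predict,
    published_decay_fit,
    simulate_percent_change_series,
    single_phase_decay,
)
from braotrial.decay_model import DecayFitError

from conftest import TRUE_K, TRUE_PLATEAU, TRUE_Y0

DAYS = np.arange(0.0, 1041.0, 30.0)


def sse(days, pct, y0, plateau, k):
    return float(np.sum((single_phase_decay(days, y0, plateau, k) - pct) ** 2))


def test_noiseless_series_recovers_parameters_exactly():
    pct = single_phase_decay(DAYS, TRUE_Y0, TRUE_PLATEAU, TRUE_K)
    fit = fit_single_phase_decay((DAYS, pct))
    assert fit.y0 == pytest.approx(TRUE_Y0, rel=1e-6)
    assert fit.plateau == pytest.approx(TRUE_PLATEAU, rel=1e-6)
    assert fit.k == pytest.approx(TRUE_K, rel=1e-6)
    assert fit.sy_x == pytest.approx(0.0, abs=1e-8)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.converged


def test_zero_decay_truth_yields_flat_curve():
    pct = np.full_like(DAYS, TRUE_Y0) + 0.001 * np.sin(DAYS)  # break SST=0
    fit = fit_single_phase_decay((DAYS, pct))
    curve = predict(fit, DAYS)
    assert np.ptp(curve) <= 0.01  # essentially constant
    assert abs(np.mean(curve) - TRUE_Y0) < 0.01


def test_predictions_from_published_curve(printed_fit):
    assert predict(printed_fit, 0.0) == pytest.approx(-9.5, abs=1e-12)
    assert predict(printed_fit, 60.0) == pytest.approx(-30.3, abs=0.05)
    assert predict(printed_fit, 1e7) == pytest.approx(-55.7, abs=1e-9)
    with pytest.raises(ValueError):
        predict(printed_fit, -1.0)


def test_prediction_decays_monotonically_to_plateau(printed_fit):
    days = np.linspace(0.0, 2000.0, 200)
    curve = predict(printed_fit, days)
    assert np.all(np.diff(curve) < 0)
    assert np.all(curve > printed_fit.plateau)


@pytest.mark.parametrize(
    "bad_series",
    [
        (np.array([0.0, 10.0, 20.0]), np.array([-10.0, -20.0, -30.0])),
        (np.full(6, 30.0), np.linspace(-10, -40, 6)),
    ],
    ids=["too_few_points", "single_day"],
)
def test_degenerate_series_raise(bad_series):
    with pytest.raises(DecayFitError):
        fit_single_phase_decay(bad_series)


def test_goodness_of_fit_perfect_and_null_cases(rng):
    pct = single_phase_decay(DAYS, TRUE_Y0, TRUE_PLATEAU, TRUE_K)
    fit = fit_single_phase_decay((DAYS, pct))
    gof = goodness_of_fit(fit, (DAYS, pct))
    assert gof["r2"] == pytest.approx(1.0, abs=1e-12)
    assert gof["p_vs_constant"] == pytest.approx(0.0, abs=1e-12)

    # trendless series: the decay model should not beat the constant model
    flat = -30.0 + rng.normal(0.0, 0.5, size=len(DAYS))
    fit_flat = fit_single_phase_decay((DAYS, flat))
    gof_flat = goodness_of_fit(fit_flat, (DAYS, flat))
    assert gof_flat["p_vs_constant"] > 0.05
    assert gof_flat["r2"] < 0.3


def test_r2_regime_depends_on_visit_schedule():
    """With %-noise SD 24 and n=38 scans, early-weighted visit days put the
    aggregate R2 near the mid-0.3s; uniform days give a weaker fit."""
    r2_uniform, r2_early = [], []
    for seed in range(30):
        rng = np.random.default_rng(5000 + seed)
        days, pct = simulate_percent_change_series(
            38, TRUE_Y0, TRUE_PLATEAU, TRUE_K, 24.0, rng=rng
        )
        fit = fit_single_phase_decay((days, pct))
        r2_uniform.append(goodness_of_fit(fit, (days, pct))["r2"])

        u = rng.uniform(0.0, 1.0, 38) ** 2
        days_e = 1040.0 * u
        pct_e = single_phase_decay(days_e, TRUE_Y0, TRUE_PLATEAU, TRUE_K)
        pct_e = pct_e + rng.normal(0.0, 24.0, 38)
        fit_e = fit_single_phase_decay((days_e, pct_e))
        r2_early.append(goodness_of_fit(fit_e, (days_e, pct_e))["r2"])
    assert 0.05 < np.mean(r2_uniform) < 0.30
    assert 0.25 < np.mean(r2_early) < 0.50


def test_estimate_never_loses_to_generating_truth():
    for seed in range(20):
        days, pct = simulate_percent_change_series(
            60, TRUE_Y0, TRUE_PLATEAU, TRUE_K, 15.0,
            rng=np.random.default_rng(seed),
        )
        fit = fit_single_phase_decay((days, pct))
        assert (
            sse(days, pct, fit.y0, fit.plateau, fit.k)
            <= sse(days, pct, TRUE_Y0, TRUE_PLATEAU, TRUE_K) + 1e-8
        )


def test_fit_is_invariant_to_point_order(rng):
    days, pct = simulate_percent_change_series(
        80, TRUE_Y0, TRUE_PLATEAU, TRUE_K, 10.0, rng=rng
    )
    fit = fit_single_phase_decay((days, pct))
    perm = rng.permutation(len(days))
    fit_perm = fit_single_phase_decay((days[perm], pct[perm]))
    assert fit.y0 == pytest.approx(fit_perm.y0, abs=1e-8)
    assert fit.plateau == pytest.approx(fit_perm.plateau, abs=1e-8)
    assert fit.k == pytest.approx(fit_perm.k, abs=1e-12)


def test_brute_force_grid_never_beats_the_optimizer():
    """A coarse 3-D grid search is an independent least-squares oracle: its
    best objective can never undercut the NLS solution."""
    y0_grid = np.linspace(-40.0, 10.0, 21)
    plateau_grid = np.linspace(-90.0, -20.0, 21)
    k_grid = np.concatenate([[0.0], np.geomspace(1e-4, 0.1, 19)])
    for seed in range(20):
        days, pct = simulate_percent_change_series(
            12, TRUE_Y0, TRUE_PLATEAU, TRUE_K, 8.0,
            rng=np.random.default_rng(100 + seed),
        )
        fit = fit_single_phase_decay((days, pct))
        nls = sse(days, pct, fit.y0, fit.plateau, fit.k)
        preds = (
            (y0_grid[:, None, None, None] - plateau_grid[None, :, None, None])
            * np.exp(-k_grid[None, None, :, None] * days[None, None, None, :])
            + plateau_grid[None, :, None, None]
        )
        grid_best = float(
            np.min(np.sum((preds - pct[None, None, None, :]) ** 2, axis=-1))
        )
        assert nls <= grid_best + 1e-9


def test_published_fit_span(printed_fit):
    assert printed_fit.span == pytest.approx(46.2)
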