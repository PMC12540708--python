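"""Grid-scan RMSE fitting: scaling, the RMSE metric, decay/affinity/delay
parameter recovery, half-life conversion and model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jnkdyn import (
    DecayRateScan,
    ExpressionProfile,
    compare_models,
    decay_halflife_convert,
    halflife_to_rate,
    minmax_scale,
    predict_cluster_halflife,
    profile_rmse,
    rate_to_halflife,
    scan_decay,
    scan_decay_affinity,
    scan_delay,
)
from jnkdyn.fitting import FitSurface, scan_decay_profiles
from jnkdyn.synthetic import gen_expression_profiles

ALPHA_STEP = (1.4 - 0.02) / 199
K_STEP = (3.0 - 0.01) / 199
DELAY_STEP = (1.0 - 0.01) / 24


def test_minmax_scale_examples():
    np.testing.assert_allclose(minmax_scale([1, 3, 5]), [0, 0.5, 1])
    np.testing.assert_allclose(minmax_scale([2, 2, 2]), [0, 0, 0])
    np.testing.assert_allclose(minmax_scale([0, 0.3, 1.0]), [0, 0.3, 1.0])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20))
def test_minmax_scale_range_and_idempotence(values):
    scaled = minmax_scale(values)
    assert scaled.min() >= 0.0 and scaled.max() <= 1.0
    np.testing.assert_allclose(minmax_scale(scaled), scaled, atol=1e-12)


def test_profile_rmse_zero_for_matching_curve():
    grid = np.arange(0, 8.01, 0.1)
    prof = ExpressionProfile("sustained", (0.0, 0.5, 1.0, 0.75, 0.25))
    model = np.interp(grid, [0, 2, 4, 6, 8], prof.values)
    assert profile_rmse(model, grid, prof) == pytest.approx(0.0, abs=1e-12)


def test_profile_rmse_hat_function_closed_form():
    """Flat model vs a 0→1 step profile: RMSE equals the RMS of the
    piecewise-linear ramp-and-plateau curve, ∫f² = (1/8)(2/3 + 6)."""
    prof = ExpressionProfile("sustained", (0.0, 1.0, 1.0, 1.0, 1.0))
    grid = np.arange(0, 8.001, 0.01)
    rmse = profile_rmse(np.zeros_like(grid), grid, prof)
    continuous = math.sqrt((2.0 / 3.0 + 6.0) / 8.0)
    assert rmse == pytest.approx(continuous, abs=0.01)
    # Riemann-sum convergence: halving the step barely changes the value
    fine = np.arange(0, 8.001, 0.005)
    assert abs(profile_rmse(np.zeros_like(fine), fine, prof) - rmse) < 1e-3


def test_profile_rmse_requires_covering_grid():
    prof = ExpressionProfile("sustained", (0.0, 0.5, 1.0), timepoints=(0.0, 4.0, 8.0))
    with pytest.raises(ValueError):
        profile_rmse(np.zeros(41), np.arange(0, 4.01, 0.1), prof)


def test_halflife_conversions():
    assert rate_to_halflife(0.693) == pytest.approx(1.0, abs=1e-3)
    assert round(halflife_to_rate(1.0 / 3.0), 1) == 2.1
    rate = 0.37
    assert halflife_to_rate(rate_to_halflife(rate)) == pytest.approx(rate, abs=1e-12)
    assert decay_halflife_convert(0.693, "rate_to_halflife") == rate_to_halflife(0.693)
    with pytest.raises(ValueError):
        rate_to_halflife(0.0)
    with pytest.raises(ValueError):
        decay_halflife_convert(1.0, "sideways")


def test_expression_profile_validation():
    with pytest.raises(ValueError):
        ExpressionProfile("sustained", (0.0, 1.5, 1.0))
    with pytest.raises(ValueError):
        ExpressionProfile("sustained", (0.0, 1.0), timepoints=(0.0, 2.0))


def test_scan_grids_match_declared_bounds(make_profile, params):
    fs = scan_decay(make_profile("sustained", 0.2), params=params)
    assert fs.alpha_grid[0] == 0.02 and fs.alpha_grid[-1] == 1.4
    assert fs.alpha_grid.size == 200
    fsd = scan_delay(
        make_profile("transient", 0.3), "mass_action_delay", params=params,
        grid_size=40,
    )
    assert fsd.delay_grid[0] == 0.01 and fsd.delay_grid[-1] == 1.0
    assert fsd.delay_grid.size == 25


def test_scan_decay_recovers_noiseless_rate(make_profile, params):
    fs = scan_decay(make_profile("sustained", 0.2), params=params)
    assert abs(fs.alpha_m_hat - 0.2) <= ALPHA_STEP + 1e-12
    assert fs.rmse_min < 0.02
    assert fs.half_life_h == pytest.approx(math.log(2) / fs.alpha_m_hat)


def test_scan_decay_rmse_is_unimodal(make_profile, params):
    fs = scan_decay(make_profile("pulsed", 0.4), params=params)
    r = fs.rmse
    interior_minima = np.flatnonzero(
        (r[1:-1] < r[:-2]) & (r[1:-1] < r[2:])
    ) + 1
    secondary = [i for i in interior_minima if r[i] > fs.rmse_min + 1e-6]
    assert not secondary


def test_scan_decay_affinity_recovers_on_grid_truth(make_profile, params):
    ag = np.linspace(0.02, 1.4, 200)
    kg = np.linspace(0.01, 3.0, 200)
    a_true = float(ag[np.argmin(np.abs(ag - 0.3))])
    k_true = float(kg[np.argmin(np.abs(kg - 0.5))])
    prof = make_profile("transient", a_true, variant="hill", K=k_true, n_target=1.8)
    fs = scan_decay_affinity(prof, n_target=1.8, params=params)
    assert abs(fs.alpha_m_hat - a_true) <= ALPHA_STEP + 1e-12
    assert abs(fs.K_hat - k_true) <= K_STEP + 1e-12
    assert fs.rmse_min < 1e-6
    # global minimum no worse than any boundary value
    assert fs.rmse_min <= fs.rmse[0].min() and fs.rmse_min <= fs.rmse[-1].min()
    assert fs.rmse_min <= fs.rmse[:, 0].min() and fs.rmse_min <= fs.rmse[:, -1].min()


def test_vanishing_K_hill_scan_equals_constant_production(make_profile, params):
    """At K → 0 the Hill promoter saturates and target production becomes
    the constant beta_t + beta_tj: the scan's RMSE row then equals an
    independently computed constant-drive fit."""
    from jnkdyn.fitting import _rmse_surface, _upstream_cached
    from jnkdyn.model import integrate_target

    prof = make_profile("transient", 0.4)
    alphas = np.linspace(0.02, 1.4, 60)
    hill_row = _rmse_surface(prof, params, "hill", alphas, Ks=np.array([1e-8]))[:, 0]

    t, _, _ = _upstream_cached(params, "transient", 8.0, 1e-3)
    const = np.full((1, t.size), params.beta_t + params.beta_tj)
    tp = np.asarray(prof.timepoints)
    tp_idx = np.searchsorted(t, tp)
    G = integrate_target(t, const, np.zeros_like(const), alphas,
                         (params.beta_t / alphas)[:, None], out_indices=tp_idx)
    cmp_times = np.arange(0.0, 8.001, 0.1)
    exp_dense = np.interp(cmp_times, tp, minmax_scale(np.asarray(prof.values)))
    for i in (0, 20, 59):
        model = minmax_scale(G[i, 0])
        dense = np.interp(cmp_times, tp, model)
        rmse = float(np.sqrt(np.mean((dense - exp_dense) ** 2)))
        # the scan's Hill term is 0 at the pJun = 0 start regardless of K,
        # so agreement holds to the width of that initial window
        assert hill_row[i] == pytest.approx(rmse, abs=1e-3)


def test_scan_delay_recovers_noiseless_delay(make_profile, params):
    prof = make_profile("pulsed", 0.5, variant="mass_action_delay", tau=0.8)
    fs = scan_delay(prof, "mass_action_delay", params=params)
    assert abs(fs.tau_hat - 0.8) <= DELAY_STEP + 1e-12
    assert abs(fs.alpha_m_hat - 0.5) <= ALPHA_STEP + 1e-12
    # nested models: ignoring the delay can only fit worse (or equal)
    no_delay = scan_decay(prof, params=params)
    assert no_delay.rmse_min >= fs.rmse_min - 1e-12


def test_scan_is_deterministic(make_profile, params):
    prof = make_profile("transient", 0.7)
    fs1 = scan_decay(prof, params=params)
    fs2 = scan_decay(prof, params=params)
    np.testing.assert_array_equal(fs1.rmse, fs2.rmse)
    assert fs1.alpha_m_hat == fs2.alpha_m_hat


def test_estimator_api_follows_sklearn_conventions(make_profile):
    est = DecayRateScan(grid_size=50)
    assert est.get_params()["grid_size"] == 50
    est.set_params(grid_size=60).fit(make_profile("sustained", 0.3))
    assert hasattr(est, "alpha_m_") and hasattr(est, "surface_")
    assert est.surface_.alpha_grid.size == 60
    with pytest.raises(TypeError):
        DecayRateScan().fit([0, 1, 2])


def test_fit_surface_tie_break_prefers_smallest_alpha():
    rmse = np.array([0.5, 0.2, 0.2, 0.4])
    fs = FitSurface(np.array([0.1, 0.2, 0.3, 0.4]), rmse)
    assert fs.alpha_m_hat == 0.2


def test_predict_cluster_halflife_recovers_with_noise(params):
    frame, _ = gen_expression_profiles(
        "sustained", np.full(5, 0.693), noise_sd=0.02, seed=11
    )
    profs = [ExpressionProfile("sustained", tuple(r)) for r in frame.to_numpy()]
    out = predict_cluster_halflife(profs, params=params)
    assert out["mean_half_life_h"] == pytest.approx(1.0, rel=0.2)
    assert out["n_genes"] == 5 and not out["single_gene"]

    single = predict_cluster_halflife(profs[:1], params=params)
    assert single["single_gene"] and single["sem_half_life_h"] == 0.0

    with pytest.raises(ValueError):
        predict_cluster_halflife([])


def test_cluster_mean_halflife_between_member_extremes(make_profile, params):
    slow = make_profile("sustained", 0.1)
    fast = make_profile("sustained", 1.2)
    out = predict_cluster_halflife([slow, fast, slow, fast], params=params)
    hls = out["half_lives_h"]
    assert hls.min() <= out["mean_half_life_h"] <= hls.max()


def test_cluster_averaged_scan_tightens_noisy_estimates(params):
    """Minimising the gene-averaged RMSE recovers the shared decay rate of
    a noisy cluster in the informative (fast-reporting) regime."""
    truth = 0.3
    frame, _ = gen_expression_profiles("pulsed", np.full(25, truth),
                                       noise_sd=0.05, seed=21)
    profs = [ExpressionProfile("pulsed", tuple(r)) for r in frame.to_numpy()]
    fs = scan_decay_profiles(profs, params=params)
    assert abs(fs.alpha_m_hat - truth) <= 3 * ALPHA_STEP


def test_compare_models_identifies_generating_model(make_profile, params):
    ag = np.linspace(0.02, 1.4, 60)
    kg = np.linspace(0.01, 3.0, 60)
    a_true = float(ag[np.argmin(np.abs(ag - 0.4))])
    k_true = float(kg[np.argmin(np.abs(kg - 1.5))])
    prof = make_profile("transient", a_true, variant="hill", K=k_true, n_target=4.0)
    table = compare_models(prof, params=params, grid_size=60, K_grid_size=60)
    assert table.iloc[0]["model"] == "hill_n4"
    # identical run is bit-identical
    table2 = compare_models(prof, params=params, grid_size=60, K_grid_size=60)
    assert table.equals(table2)


def test_hill_models_nest_mass_action(make_profile, params):
    prof = make_profile("sustained", 0.35)
    table = compare_models(prof, params=params, grid_size=60, K_grid_size=60)
    best = {r["model"]: r["rmse_min"] for _, r in table.iterrows()}
    assert best["hill_n1.8"] <= best["mass_action"] + 0.02
    assert best["hill_n4"] <= best["mass_action"] + 0.02
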