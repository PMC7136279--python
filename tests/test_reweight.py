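"""Maximum-entropy reweighting: identities, oracles and recovery."""

import numpy as np
import pytest

from hdxens.errors import InputError
from hdxens.features import FeatureTable
from hdxens.forward import DeuterationSeries, ForwardModelParams, Segment
from hdxens.reweight import (
    KB_KJ_MOL,
    EnsembleWeights,
    MaxEntReweighting,
    apparent_work,
    apparent_work_kl,
    kish_ess,
    lambda_step,
    log_error_density,
    mc_optimize_betas,
    mean_squared_deviation,
    omega_weights,
    run_reweighting,
)
from hdxens.synthetic import TwoStateSpec, two_state_problem, uniform_rates

from conftest import tiny_feature_table


def _single_observable_table(values):
    """One exchangeable residue whose observable b equals the given values
    (beta_H = 1, N_H carries the value)."""
    values = np.asarray(values, dtype=float)
    residues = np.array([1, 2])
    nc = np.zeros((values.size, 2))
    nh = np.column_stack([np.zeros_like(values), values])
    return FeatureTable(residues, nc, nh, np.array([False, True]))


def test_omega_zero_lambda_is_uniform():
    table = tiny_feature_table()
    w = omega_weights(np.zeros(3), table, ForwardModelParams())
    np.testing.assert_allclose(w.values, 1 / 3)


def test_omega_hand_example():
    # observable b = (1, 2), lambda = ln 2 -> weights proportional to (2, 4)
    table = _single_observable_table([1.0, 2.0])
    params = ForwardModelParams(beta_c=0.0, beta_h=1.0)
    w = omega_weights(np.array([np.log(2.0)]), table, params)
    np.testing.assert_allclose(w.values, [1 / 3, 2 / 3], atol=1e-12)


def test_omega_single_frame():
    table = _single_observable_table([3.0])
    w = omega_weights(np.array([0.7]), table, ForwardModelParams(0.0, 1.0))
    np.testing.assert_allclose(w.values, [1.0])


def test_omega_rejects_nonfinite_lambda():
    with pytest.raises(InputError):
        omega_weights(np.array([np.nan]), _single_observable_table([1.0]),
                      ForwardModelParams(0.0, 1.0))


def test_apparent_work_zero_bias():
    table = tiny_feature_table()
    assert apparent_work(np.zeros(3), table, ForwardModelParams()) == 0.0


def test_apparent_work_equals_kl_hand_value():
    # Omega = (1/3, 2/3): d_KL = (1/3)ln(1/3) + (2/3)ln(2/3) + ln 2
    table = _single_observable_table([1.0, 2.0])
    params = ForwardModelParams(0.0, 1.0)
    lam = np.array([np.log(2.0)])
    w_eq = apparent_work(lam, table, params, temperature=300.0)
    dkl = (1 / 3) * np.log(1 / 3) + (2 / 3) * np.log(2 / 3) + np.log(2)
    assert dkl == pytest.approx(0.0566, abs=2e-4)
    assert w_eq == pytest.approx(KB_KJ_MOL * 300 * dkl, rel=1e-12)
    w_kl = apparent_work_kl(omega_weights(lam, table, params))
    assert w_eq == pytest.approx(w_kl, rel=1e-10)


def test_apparent_work_concentration_limit():
    # nearly all mass on one of N frames -> W_app -> k_B T ln N
    table = _single_observable_table([0.0, 0.0, 0.0, 40.0])
    params = ForwardModelParams(0.0, 1.0)
    w = apparent_work(np.array([2.0]), table, params)
    assert w == pytest.approx(KB_KJ_MOL * 300 * np.log(4), rel=1e-3)


def test_kl_identity_on_random_lambdas():
    """Eq-style apparent work agrees with the KL form to 1e-8 relative."""
    prob = two_state_problem(TwoStateSpec(n_frames=50, n_residues=8, seed=2))
    rng = np.random.default_rng(0)
    params = ForwardModelParams()
    n = prob.features.exchangeable.sum()
    for _ in range(5):
        lam = rng.normal(0, 0.2, n)
        w_eq = apparent_work(lam, prob.features, params)
        w_kl = apparent_work_kl(omega_weights(lam, prob.features, params))
        assert w_eq == pytest.approx(w_kl, rel=1e-8, abs=1e-12)


def _series(values, segs=None, times=None):
    values = np.atleast_2d(values)
    segs = segs or [Segment(i, i + 1) for i in range(1, values.shape[0] + 1)]
    times = times if times is not None else list(range(1, values.shape[1] + 1))
    return DeuterationSeries(segs, times, values)


def test_log_error_density_values():
    a = _series([[0.4, 0.5]])
    assert log_error_density(a, a, gamma=10) == 0.0
    b = _series([[0.5, 0.5]])
    assert log_error_density(b, a, gamma=100) == pytest.approx(-0.5)
    assert log_error_density(b, a, gamma=200) == pytest.approx(-1.0)


def test_msd_values_and_loop_oracle():
    a = _series([[0.1, 0.2], [0.3, 0.4]])
    b = _series([[0.2, 0.3], [0.4, 0.5]])
    assert mean_squared_deviation(a, a) == 0.0
    assert mean_squared_deviation(a, b) == pytest.approx(0.01)
    rng = np.random.default_rng(4)
    x = _series(rng.uniform(0, 1, (3, 4)))
    y = _series(rng.uniform(0, 1, (3, 4)))
    acc = 0.0
    for i in range(3):
        for j in range(4):
            acc += (x.values[i, j] - y.values[i, j]) ** 2
    assert mean_squared_deviation(x, y) == pytest.approx(acc / 12)


def test_kish_effective_sample_size():
    assert kish_ess(EnsembleWeights.uniform(17)) == pytest.approx(17.0)
    w = np.zeros(9)
    w[3] = 1.0
    assert kish_ess(w) == pytest.approx(1.0)
    assert kish_ess(np.array([0.5, 0.25, 0.25])) == pytest.approx(1 / 0.375)


def test_lambda_step_undamped_returns_gradient_and_fixed_point():
    prob = two_state_problem(TwoStateSpec(n_frames=40, n_residues=6, seed=3))
    params = ForwardModelParams()
    n = prob.features.exchangeable.sum()
    lam0 = np.zeros(n)
    g = lambda_step(lam0, prob.features, prob.target, prob.rates, params,
                    gamma=10.0, update_rate=1.0)
    half = lambda_step(lam0, prob.features, prob.target, prob.rates, params,
                       gamma=10.0, update_rate=0.5)
    np.testing.assert_allclose(half, 0.5 * g, atol=1e-12)
    # at a converged fixed point the update leaves lambda unchanged
    model = MaxEntReweighting(prob.features, prob.target, prob.rates)
    fit = model.fit(10.0)
    assert fit.converged
    lam_star = fit.lambdas
    # tol=1e-8 at nominal rate 0.01 bounds the residual |g - lambda| by 1e-6
    stepped = lambda_step(lam_star, prob.features, prob.target, prob.rates,
                          params, gamma=10.0, update_rate=1.0)
    np.testing.assert_allclose(stepped, lam_star, rtol=0, atol=1e-6)


def test_converged_lambda_matches_dense_grid_oracle():
    """Tiny problem (2 frames, 1 residue, 1 time): the converged lambda and
    likelihood match a dense 1-D grid minimization of L."""
    table = _single_observable_table([1.0, 3.0])
    rates = uniform_rates(2, 1.0)
    target = DeuterationSeries([Segment(1, 2)], [2.0], [[0.35]])
    params = ForwardModelParams(0.0, 1.0)
    model = MaxEntReweighting(table, target, rates, params=params)
    res = model.fit(50.0, tol=1e-12)
    assert res.converged

    b = np.array([1.0, 3.0])

    def L(lam):
        logw = b * lam
        s = logw.max()
        w = np.exp(logw - s)
        om = w / w.sum()
        lnp = float(om @ b)
        d = 1 - np.exp(-2.0 * np.exp(-lnp))
        ln_rho = -50.0 * (d - 0.35) ** 2 / 2
        wapp = lam * lnp + np.log(2) - (s + np.log(w.sum()))
        return wapp - ln_rho

    # zooming dense grid search, independent of the iterative path
    lo, hi = -10.0, 10.0
    for _ in range(8):
        grid = np.linspace(lo, hi, 2001)
        vals = [L(x) for x in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 2000)]
    lam_star = 0.5 * (lo + hi)
    assert abs(res.lambdas[0] - lam_star) < 1e-4
    assert abs(res.likelihood - L(lam_star)) < 1e-6


def test_self_consistent_target_gives_zero_bias(small_problem):
    """A target equal to the unweighted prediction leaves weights uniform."""
    from hdxens.forward import ensemble_lnP
    from hdxens.targets import build_target, residue_segments

    feats = small_problem.features
    lnp = ensemble_lnP(
        feats, EnsembleWeights.uniform(feats.n_frames), ForwardModelParams()
    )
    target = build_target(
        lnp, small_problem.rates,
        residue_segments(feats.residues[feats.exchangeable]),
        [0.167, 1.0, 10.0, 60.0, 120.0],
    )
    res = MaxEntReweighting(feats, target, small_problem.rates).fit(1e3)
    assert np.max(np.abs(res.lambdas)) < 1e-3
    assert res.w_app < 1e-6
    np.testing.assert_allclose(
        res.weights.values, 1 / feats.n_frames, atol=1e-6
    )


def test_weights_normalized_and_msd_small_after_fit(small_problem):
    res = run_reweighting(
        small_problem.features, small_problem.target, small_problem.rates, 1e3
    )
    assert res.weights.values.sum() == pytest.approx(1.0, abs=1e-12)
    assert res.msd < 1e-8
    assert res.w_app >= 0
    assert res.w_app == pytest.approx(res.w_app_kl, rel=1e-8, abs=1e-12)


def test_likelihood_nonincreasing_over_accepted_iterations(small_problem):
    res = run_reweighting(
        small_problem.features, small_problem.target, small_problem.rates, 1e2
    )
    accepted = res.history[res.history.accepted == 1]
    diffs = np.diff(accepted.likelihood.to_numpy())
    assert np.all(diffs <= 1e-9)


def test_mc_beta_moves_never_increase_msd(small_problem):
    params = ForwardModelParams(0.2, 5.0)
    model = MaxEntReweighting(
        small_problem.features, small_problem.target, small_problem.rates,
        params=params,
    )
    n = small_problem.features.exchangeable.sum()
    lam = np.zeros(n)
    msd0 = mean_squared_deviation(model.predict(params=params),
                                  small_problem.target)
    out = mc_optimize_betas(
        lam, small_problem.features, small_problem.target,
        small_problem.rates, params, n_trials=50, seed=9,
    )
    msd1 = mean_squared_deviation(model.predict(params=out),
                                  small_problem.target)
    assert msd1 <= msd0
    # determinism given the seed
    out2 = mc_optimize_betas(
        lam, small_problem.features, small_problem.target,
        small_problem.rates, params, n_trials=50, seed=9,
    )
    assert (out.beta_c, out.beta_h) == (out2.beta_c, out2.beta_h)


def test_beta_recovery_on_self_consistent_target(small_problem):
    """Full reweighting with MC beta optimization, started off-target at
    (0.30, 3.0), recovers the generative (0.35, 2.0)."""
    from hdxens.forward import ensemble_lnP
    from hdxens.targets import build_target, residue_segments

    feats = small_problem.features
    lnp = ensemble_lnP(
        feats, EnsembleWeights.uniform(feats.n_frames), ForwardModelParams()
    )
    target = build_target(
        lnp, small_problem.rates,
        residue_segments(feats.residues[feats.exchangeable]),
        [0.167, 1.0, 10.0, 60.0, 120.0],
    )
    res = MaxEntReweighting(feats, target, small_problem.rates).fit(
        1e3, optimize_betas=True, seed=5,
        params0=ForwardModelParams(0.30, 3.0), max_iter=5000,
    )
    assert res.params.beta_c == pytest.approx(0.35, abs=0.02)
    assert res.params.beta_h == pytest.approx(2.0, abs=0.2)


def test_gamma_scan_warm_start_monotone(small_problem):
    model = MaxEntReweighting(
        small_problem.features, small_problem.target, small_problem.rates
    )
    curve = model.gamma_scan([1.0, 10.0, 100.0, 1000.0])
    assert np.all(np.diff(curve.w_app) >= -1e-9)
    assert np.all(np.diff(curve.msd) <= 1e-12)
    with pytest.raises(InputError):
        model.gamma_scan([10.0])
    with pytest.raises(InputError):
        model.gamma_scan([10.0, 1.0])


def test_results_summary_mentions_key_quantities(small_problem):
    res = run_reweighting(
        small_problem.features, small_problem.target, small_problem.rates, 10.0
    )
    text = res.summary()
    for token in ("gamma", "MSD", "W_app", "Kish", "beta_C"):
        assert token in text
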