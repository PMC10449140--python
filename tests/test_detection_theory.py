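"""Energy-detector closed forms, sample-complexity and Monte-Carlo checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from bciwall import (
    design_detector,
    detectable,
    p_detection,
    p_false_alarm,
    q_function,
    q_inverse,
    samples_required_stationary,
    samples_required_uncertain,
    simulate_energy_detector,
)


def test_q_function_landmarks():
    assert q_function(0.0) == pytest.approx(0.5, abs=1e-12)
    assert q_function(1.6449) == pytest.approx(0.05, abs=1e-4)
    assert q_inverse(0.5) == pytest.approx(0.0, abs=1e-12)


def test_q_inverse_pair():
    xs = np.linspace(-6, 6, 41)
    np.testing.assert_allclose(q_inverse(q_function(xs)), xs, atol=1e-9)
    ps = np.logspace(-9, -0.001, 30)
    np.testing.assert_allclose(q_function(q_inverse(ps)), ps, rtol=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(1e-9, 1.0 - 1e-9))
def test_q_pair_holds_across_the_unit_interval(p):
    assert float(q_function(q_inverse(p))) == pytest.approx(p, rel=1e-9, abs=1e-12)


def test_p_false_alarm_at_the_mean_is_half():
    assert p_false_alarm(gamma=1.3 * 2.0, sigma2=2.0, n=50, rho=1.3) == pytest.approx(0.5)


def test_p_false_alarm_decreasing_in_gamma():
    gammas = np.linspace(0.5, 3.0, 50)
    vals = [p_false_alarm(g, 1.0, 30) for g in gammas]
    assert np.all(np.diff(vals) < 0)


def test_p_detection_at_the_mean_is_half_and_rho1_reduces():
    assert p_detection(gamma=1.5, t_c=0.5, sigma2=1.0, n=100, rho=1.0) == pytest.approx(0.5)
    # with rho = 1 the uncertain form equals the stationary form
    for g in (1.1, 1.4, 2.0):
        stationary = q_function((g - 1.5) / (math.sqrt(2 / 100) * 1.5))
        assert p_detection(g, 0.5, 1.0, 100, rho=1.0) == pytest.approx(float(stationary))


def test_samples_required_stationary_scaling():
    n1 = samples_required_stationary(0.05, 0.95, 0.01, ceil=False)
    n2 = samples_required_stationary(0.05, 0.95, 0.001, ceil=False)
    assert n2 / n1 == pytest.approx(100.0, rel=0.05)  # ~1/SNR^2 at small SNR


def test_samples_required_stationary_against_threshold_solver():
    """N from the closed form admits a gamma meeting both targets."""
    p_fa, p_d, snr = 0.05, 0.95, 0.1
    n = samples_required_stationary(p_fa, p_d, snr)

    def mismatch(gamma):
        return p_false_alarm(gamma, 1.0, n) - p_fa

    gamma = optimize.brentq(mismatch, 1.0, 3.0)
    assert p_detection(gamma, snr, 1.0, n) >= p_d - 0.005


def test_samples_required_uncertain_wall_behaviour():
    rho = 1.5
    wall = rho - 1 / rho
    assert samples_required_uncertain(0.05, 0.95, wall, rho) == math.inf
    assert samples_required_uncertain(0.05, 0.95, 0.9 * wall, rho) == math.inf
    assert math.isfinite(samples_required_uncertain(0.05, 0.95, 1.1 * wall, rho))


def test_samples_required_uncertain_monotone_above_wall():
    rho = 1.3
    wall = rho - 1 / rho
    snrs = wall * (1 + np.logspace(-3, 1, 25))
    ns = [samples_required_uncertain(0.05, 0.95, s, rho, ceil=False) for s in snrs]
    assert np.all(np.diff(ns) < 0)
    # diverges towards the wall
    assert ns[0] > 1e6


def test_uncertain_rho1_matches_stationary_low_snr_limit():
    for snr in (1e-3, 1e-4):
        n_u = samples_required_uncertain(0.05, 0.95, snr, 1.0, ceil=False)
        n_s = samples_required_stationary(0.05, 0.95, snr, ceil=False)
        assert n_u / n_s == pytest.approx(1.0, rel=5 * snr)


def test_wall_consistency_with_decision_rule():
    for rho in (1.2, 2.0, 13.21):
        wall_db = 10 * np.log10(rho - 1 / rho)
        for snr_db_val in (wall_db - 1, wall_db + 1):
            snr_lin = 10 ** (snr_db_val / 10)
            finite = math.isfinite(samples_required_uncertain(0.05, 0.95, snr_lin, rho))
            assert finite == detectable(snr_db_val, wall_db)


def test_decision_rule_worked_examples():
    assert not detectable(-8.71, 11.18)  # fullband jaw clench
    assert detectable(7.0, 5.0)  # alpha-band jaw clench
    assert not detectable(3.0, 3.0)  # strict inequality


def test_simulation_is_deterministic_and_null_consistent():
    kwargs = dict(t_c=0.0, sigma2_schedule=1.0, n=50, gamma=1.3, trials=20000)
    r1 = simulate_energy_detector(seed=123, **kwargs)
    r2 = simulate_energy_detector(seed=123, **kwargs)
    assert r1 == r2
    p_fa_emp, p_d_emp = r1
    se = math.sqrt(0.25 / 20000)
    assert abs(p_fa_emp - p_d_emp) < 4 * se  # no signal: the hypotheses coincide


def test_monte_carlo_matches_stationary_closed_forms():
    # moderate rates at a few hundred samples: the regime the asymptotic
    # formulas are built for
    n, gamma, t_c, trials = 400, 1.05, 0.12, 100_000
    p_fa_emp, p_d_emp = simulate_energy_detector(
        t_c=t_c, sigma2_schedule=1.0, n=n, gamma=gamma, trials=trials, seed=7
    )
    for emp, theory in (
        (p_fa_emp, p_false_alarm(gamma, 1.0, n)),
        (p_d_emp, p_detection(gamma, t_c, 1.0, n)),
    ):
        se = math.sqrt(theory * (1 - theory) / trials) + 2e-3  # residual skewness
        assert abs(emp - theory) < 3 * se


def test_monte_carlo_matches_uncertain_worst_case():
    """Adversarial schedule: loud noise under H0, quiet noise under H1."""
    rho, sigma2, n, gamma, t_c, trials = 1.3, 1.0, 1000, 1.358, 0.53, 100_000
    p_fa_emp, p_d_emp = simulate_energy_detector(
        t_c=t_c,
        sigma2_schedule=rho * sigma2,
        sigma2_schedule_h1=sigma2 / rho,
        n=n,
        gamma=gamma,
        trials=trials,
        seed=8,
    )
    p_fa_th = p_false_alarm(gamma, sigma2, n, rho)
    p_d_th = p_detection(gamma, t_c, sigma2, n, rho)
    assert abs(p_fa_emp - p_fa_th) < 3 * math.sqrt(p_fa_th * (1 - p_fa_th) / trials) + 5e-3
    assert abs(p_d_emp - p_d_th) < 3 * math.sqrt(p_d_th * (1 - p_d_th) / trials) + 5e-3


def test_design_detector_bundle():
    d = design_detector(0.05, 0.95, snr_linear=0.5, rho=1.2, sigma2=1.0)
    assert math.isfinite(d.n_samples)
    assert d.n_samples >= d.n_samples_raw
    assert p_false_alarm(d.gamma, 1.0, int(d.n_samples), 1.2) == pytest.approx(0.05, abs=1e-6)
    below = design_detector(0.05, 0.95, snr_linear=0.1, rho=1.5)
    assert below.n_samples == math.inf


def test_parameter_validation():
    with pytest.raises(ValueError):
        q_inverse(0.0)
    with pytest.raises(ValueError):
        samples_required_stationary(0.5, 0.5, 0.1)
    with pytest.raises(ValueError):
        p_false_alarm(1.0, 1.0, 0)
    with pytest.raises(ValueError):
        samples_required_uncertain(0.05, 0.95, 0.1, 0.5)
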