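"""Sliding-window power, noise uncertainty and the SNR-wall."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bciwall import (
    AnalysisConfig,
    Recording,
    apply_chain,
    design_chain,
    mean_square_power,
    noise_extrema,
    profile_recording,
    rho,
    sliding_power,
    snr_wall_db,
)
from bciwall.snr_wall import SlidingPowerSeries

FS = 250.0


def brute_force_sliding_power(x, window, stride):
    return np.array(
        [np.mean(x[i : i + window] ** 2) for i in range(0, len(x) - window + 1, stride)]
    )


def test_constant_signal_power_is_amplitude_squared():
    rec = Recording(np.full(1000, 3e-5), fs=FS)
    sps = sliding_power(rec, window_s=2.0)
    np.testing.assert_allclose(sps.powers, 9e-10, rtol=1e-12)


def test_alternating_unit_signal_has_unit_power():
    rec = Recording(np.tile([1.0, -1.0], 500), fs=FS)
    sps = sliding_power(rec, window_s=1.0)
    np.testing.assert_allclose(sps.powers, 1.0, rtol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    window=st.integers(10, 200),
    stride=st.integers(1, 40),
)
def test_sliding_power_matches_brute_force_on_arbitrary_noise(seed, window, stride):
    rng = np.random.default_rng(seed)
    x = rng.normal(scale=rng.uniform(1e-6, 1e-3), size=1000)
    sps = sliding_power(Recording(x, fs=FS), window_s=window / FS, stride=stride)
    np.testing.assert_allclose(
        sps.powers, brute_force_sliding_power(x, window, stride), rtol=1e-12
    )


@pytest.mark.parametrize("stride", [1, 7, 125])
def test_sliding_power_matches_brute_force(stride):
    rng = np.random.default_rng(42)
    x = rng.normal(scale=2e-5, size=1000)
    window = int(0.5 * FS)
    sps = sliding_power(Recording(x, fs=FS), window_s=0.5, stride=stride)
    expected = brute_force_sliding_power(x, window, stride)
    assert sps.powers.size == (1000 - window) // stride + 1
    np.testing.assert_allclose(sps.powers, expected, rtol=1e-12)


def test_recording_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="window"):
        sliding_power(Recording(np.ones(100), fs=FS), window_s=2.0)


def test_noise_extrema_examples():
    sps = SlidingPowerSeries(np.array([4e-10, 1e-10, 9e-10]), 2.0, 1, FS)
    assert noise_extrema(sps) == (1e-10, 9e-10)
    flat = SlidingPowerSeries(np.full(5, 2e-10), 2.0, 1, FS)
    lo, hi = noise_extrema(flat)
    assert lo == hi


def test_flatlined_channel_is_a_degenerate_input():
    sps = SlidingPowerSeries(np.array([0.0, 1e-10]), 2.0, 1, FS)
    with pytest.raises(ValueError, match="zero"):
        noise_extrema(sps)


def test_two_segment_noise_recovers_std_ratio():
    rng = np.random.default_rng(3)
    x = np.r_[rng.normal(scale=1.0, size=5000), rng.normal(scale=10.0, size=5000)]
    sps = sliding_power(Recording(x, fs=FS), window_s=2.0)
    lo, hi = noise_extrema(sps)
    assert lo == pytest.approx(1.0, rel=0.25)
    assert hi == pytest.approx(100.0, rel=0.25)


def test_rho_is_a_ratio_of_standard_deviations():
    # worked example: printed extrema give ~13.2
    assert rho(1.15e-10, 2.00e-8) == pytest.approx(13.21, rel=0.01)
    assert rho(1e-10, 4e-10) == pytest.approx(2.0, rel=1e-12)
    assert rho(5e-10, 5e-10) == 1.0
    with pytest.raises(ValueError):
        rho(0.0, 1e-10)


def test_snr_wall_db_values():
    assert snr_wall_db(13.21) == pytest.approx(11.18, abs=5e-3)
    assert snr_wall_db(2.0) == pytest.approx(10 * np.log10(1.5), abs=1e-9)
    assert snr_wall_db(1.0) == float("-inf")
    with pytest.raises(ValueError):
        snr_wall_db(0.9)


def test_snr_wall_strictly_increasing_in_rho():
    rhos = np.linspace(1.001, 50, 300)
    walls = np.array([snr_wall_db(r) for r in rhos])
    assert np.all(np.diff(walls) > 0)


def test_stationary_noise_has_a_low_wall():
    rng = np.random.default_rng(11)
    rec = Recording(rng.normal(scale=2e-5, size=int(120 * FS)), fs=FS)
    prof = profile_recording(rec, AnalysisConfig())
    assert prof.rho < 1.6
    assert prof.snr_wall_db < 1.0


def test_single_window_recording_degenerates_to_rho_one():
    rng = np.random.default_rng(12)
    rec = Recording(rng.normal(size=int(2 * FS)), fs=FS)
    prof = profile_recording(rec, AnalysisConfig(discard_startup_s=0.0))
    assert prof.sigma2_min == prof.sigma2_max
    assert prof.sigma2_nominal == pytest.approx(prof.sigma2_min, rel=1e-12)
    assert prof.rho == 1.0 and prof.snr_wall_db == float("-inf")


def test_tiling_window_mean_equals_whole_recording_power():
    rng = np.random.default_rng(13)
    window = int(2 * FS)
    x = rng.normal(size=10 * window)
    sps = sliding_power(Recording(x, fs=FS), window_s=2.0, stride=window)
    assert sps.powers.mean() == pytest.approx(mean_square_power(x), rel=1e-12)
    assert sps.powers.min() <= mean_square_power(x) <= sps.powers.max()


def test_stride_robustness_of_rho():
    from bciwall.synthetic import generate_recording, task_preset

    rec, _ = generate_recording(task_preset("jaw_clench", seed=5))
    filt = apply_chain(design_chain("fullband", FS, 50.0), rec)
    prof1 = profile_recording(filt, AnalysisConfig(stride=1))
    prof25 = profile_recording(filt, AnalysisConfig(stride=25))  # fs/10
    assert prof25.rho == pytest.approx(prof1.rho, rel=0.02)


def test_profile_scale_invariance():
    rng = np.random.default_rng(14)
    x = rng.normal(scale=2e-5, size=int(30 * FS))
    base = profile_recording(Recording(x, fs=FS), AnalysisConfig())
    scaled = profile_recording(Recording(1e3 * x, fs=FS), AnalysisConfig())
    assert scaled.rho == pytest.approx(base.rho, abs=1e-12)
    assert scaled.snr_wall_db == pytest.approx(base.snr_wall_db, abs=1e-9)
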