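"""Epoching, referencing, averaging, laterality and component windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presaccade import erp as E
from presaccade.errors import AlignmentError, InvalidSignalError, RereferenceError
from presaccade.phantom import raw_times


def _raw_epochset(n_trials=3, n_ch=4, trials=None, data=None):
    times = raw_times()
    if data is None:
        data = np.zeros((n_trials, n_ch, times.size))
    if trials is None:
        trials = pd.DataFrame(
            {
                "movement": ["prosaccade"] * n_trials,
                "cue": ["cued"] * n_trials,
                "procedure": ["mixed"] * n_trials,
                "side": ["right"] * n_trials,
                "rt_ms": [400.0] * n_trials,
                "error": [False] * n_trials,
                "blink": [False] * n_trials,
            }
        )
    return E.EpochSet(data, times, [f"E{i+1}" for i in range(n_ch)], trials, "raw")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def test_target_locked_epoch_has_476_samples():
    ep = E.segment_epochs(_raw_epochset(), "target")
    assert ep.data.shape[-1] == 476
    assert ep.times[0] == -1100.0 and ep.times[-1] == 800.0


def test_saccade_locked_epoch_contains_time_zero():
    ep = E.segment_epochs(_raw_epochset(), "saccade")
    assert 0.0 in ep.times
    assert ep.times[0] == -300.0 and ep.times[-1] == 100.0


def test_catch_trials_excluded_from_saccade_locking():
    trials = pd.DataFrame(
        {
            "movement": ["prosaccade", "catch"],
            "cue": ["cued"] * 2,
            "procedure": ["mixed"] * 2,
            "side": ["left", "right"],
            "rt_ms": [400.0, np.nan],
            "error": [False] * 2,
            "blink": [False] * 2,
        }
    )
    ep = E.segment_epochs(_raw_epochset(n_trials=2, trials=trials), "saccade")
    assert ep.n_trials == 1
    assert (ep.trials["movement"] == "prosaccade").all()


def test_saccade_locked_window_follows_saccade_onset():
    times = raw_times()
    data = np.zeros((1, 2, times.size))
    data[0, :, :] = times[None, :]  # waveform equals time, in uV
    trials = pd.DataFrame(
        {"movement": ["prosaccade"], "cue": ["cued"], "procedure": ["mixed"],
         "side": ["right"], "rt_ms": [400.0], "error": [False], "blink": [False]}
    )
    ep = E.segment_epochs(_raw_epochset(n_trials=1, n_ch=2, trials=trials, data=data), "saccade")
    # sample at saccade-locked t=0 is the raw sample at 400 ms
    np.testing.assert_allclose(ep.data[0, :, ep.times == 0.0], 400.0)


# ---------------------------------------------------------------------------
# Rejection and referencing
# ---------------------------------------------------------------------------

def test_reject_trials_removes_flagged():
    n = 100
    trials = pd.DataFrame(
        {
            "movement": ["prosaccade"] * n,
            "cue": ["cued"] * n,
            "procedure": ["mixed"] * n,
            "side": ["right"] * n,
            "rt_ms": [400.0] * n,
            "error": [i < 4 for i in range(n)],
            "blink": [4 <= i < 7 for i in range(n)],
        }
    )
    ep = E.segment_epochs(_raw_epochset(n_trials=n, trials=trials), "target")
    assert E.reject_trials(ep).n_trials == 93
    # no flags -> identity
    clean = trials.assign(error=False, blink=False)
    ep2 = E.segment_epochs(_raw_epochset(n_trials=n, trials=clean), "target")
    assert E.reject_trials(ep2).n_trials == n
    # all flagged -> empty set with warning
    bad = trials.assign(error=True)
    ep3 = E.segment_epochs(_raw_epochset(n_trials=n, trials=bad), "target")
    with pytest.warns(UserWarning):
        assert E.reject_trials(ep3).n_trials == 0


def test_average_reference_zeroes_constant_and_is_idempotent():
    ep = _raw_epochset(n_trials=1, n_ch=5)
    ep.data[:] = 5.0
    ref = E.rereference_average(ep)
    np.testing.assert_allclose(ref.data, 0.0, atol=1e-12)
    rng = np.random.default_rng(0)
    ep.data[:] = rng.normal(size=ep.data.shape)
    once = E.rereference_average(ep)
    twice = E.rereference_average(once)
    np.testing.assert_allclose(once.data, twice.data, atol=1e-12)
    np.testing.assert_allclose(once.data.mean(axis=1), 0.0, atol=1e-9)


def test_average_reference_needs_two_channels():
    ep = _raw_epochset(n_trials=1, n_ch=1)
    with pytest.raises(RereferenceError):
        E.rereference_average(ep)


def test_zero_mean_pair_unchanged_by_reference():
    ep = _raw_epochset(n_trials=1, n_ch=2)
    ep.data[0, 0, :] = 1.0
    ep.data[0, 1, :] = -1.0
    np.testing.assert_allclose(E.rereference_average(ep).data, ep.data)


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------

def test_erp_of_identical_trials_equals_single_trial():
    ep = E.segment_epochs(_raw_epochset(n_trials=4, n_ch=3), "target")
    ep.data[:] = np.arange(ep.data.shape[-1])[None, None, :]
    erps = E.compute_erp(ep, baseline_window=None)
    np.testing.assert_allclose(erps[()].data, ep.data[0])
    assert erps[()].n_trials == 4


def test_erp_of_opposite_trials_is_zero():
    ep = E.segment_epochs(_raw_epochset(n_trials=2, n_ch=2), "target")
    rng = np.random.default_rng(1)
    a = rng.normal(size=ep.data.shape[1:])
    ep.data[0], ep.data[1] = a, -a
    erps = E.compute_erp(ep, baseline_window=None)
    np.testing.assert_allclose(erps[()].data, 0.0, atol=1e-12)


def test_erp_recovers_planted_ramp_within_standard_error():
    """ERP of ramp + white noise stays within 4 SE of the ramp everywhere."""
    n, sd = 300, 2.0
    ep = E.segment_epochs(_raw_epochset(n_trials=n, n_ch=2), "target")
    ramp = np.clip((ep.times + 1000) / 1000, 0, 1) * -6.0
    rng = np.random.default_rng(2)
    ep.data[:] = ramp[None, None, :] + rng.normal(0, sd, ep.data.shape)
    erp = E.compute_erp(ep, baseline_window=None)[()]
    bound = 4 * sd / np.sqrt(n)
    assert np.abs(erp.data - ramp[None, :]).max() < bound


def test_empty_condition_cell_warns():
    ep = E.segment_epochs(_raw_epochset(n_trials=0), "target")
    with pytest.warns(UserWarning):
        out = E.compute_erp(ep)
    assert out == {}


# ---------------------------------------------------------------------------
# Laterality
# ---------------------------------------------------------------------------

def test_flip_lateral_swaps_parietal_pairs(montage):
    times = np.arange(-300.0, 101.0, 4.0)
    data = np.arange(len(montage.channels), dtype=float)[:, None] * np.ones_like(times)
    left = E.ERPWave({"side": "left"}, data, times, list(montage.channels), "saccade", 1)
    flipped = E.flip_lateral(left, montage)
    i3 = montage.index("E52")  # Parietal3 member
    i4 = montage.index("E80")  # its Parietal4 partner
    np.testing.assert_allclose(flipped.data[i3], left.data[i4])
    np.testing.assert_allclose(flipped.data[i4], left.data[i3])
    # midline channels unchanged
    iz = montage.index("E61")
    np.testing.assert_allclose(flipped.data[iz], left.data[iz])
    # involution
    again = E.flip_lateral(flipped, montage, side="left")
    np.testing.assert_allclose(again.data, left.data)
    # right-side ERPs untouched
    right = E.ERPWave({"side": "right"}, data, times, list(montage.channels), "saccade", 1)
    np.testing.assert_allclose(E.flip_lateral(right, montage).data, data)


# ---------------------------------------------------------------------------
# Component measures
# ---------------------------------------------------------------------------

def _target_erp(wave):
    times = np.arange(-1100.0, 801.0, 4.0)
    data = np.tile(wave(times), (2, 1))
    return E.ERPWave({}, data, times, ["E61", "E68"], "target", 1)


def _saccade_erp(wave):
    times = np.arange(-300.0, 101.0, 4.0)
    data = np.tile(wave(times), (2, 1))
    return E.ERPWave({}, data, times, ["E61", "E68"], "saccade", 1)


def test_negsw_of_linear_ramp_is_minus_5_70():
    erp = _target_erp(
        lambda t: np.where(t <= -1000, 0.0, np.where(t <= 0, -6 * (t + 1000) / 1000, -6.0))
    )
    v = E.measure_component(erp, "pretarget_neg_sw", "E61").value_uv
    assert v == pytest.approx(-5.70, abs=1e-9)


def test_negsw_insensitive_to_constant_offsets():
    base = _target_erp(lambda t: np.clip((t + 1000) / 1000, 0, 1) * -6.0)
    shifted = _target_erp(lambda t: np.clip((t + 1000) / 1000, 0, 1) * -6.0 + 3.7)
    v0 = E.measure_component(base, "pretarget_neg_sw", "E61").value_uv
    v1 = E.measure_component(shifted, "pretarget_neg_sw", "E61").value_uv
    assert v0 == pytest.approx(v1, abs=1e-12)


def test_spike_of_gaussian_matches_sampled_evaluation_oracle():
    """Planted 3-uV, sigma 5 ms Gaussian: measure equals the independent
    window arithmetic on the Gaussian evaluated at the 4-ms samples."""
    A, s = 3.0, 5.0
    erp = _saccade_erp(lambda t: A * np.exp(-(t**2) / (2 * s**2)))
    got = E.measure_component(erp, "spike", "E61").value_uv

    def g(t):
        return A * np.exp(-(t**2) / (2 * s**2))

    # trapezoid window mean written out longhand: endpoints half-weighted
    def win(lo, hi):
        ts = np.arange(lo, hi + 1, 4.0)
        return (g(ts[0]) / 2 + g(ts[1:-1]).sum() + g(ts[-1]) / 2) * 4.0 / (hi - lo)

    expected = win(-8.0, 8.0) - win(-24.0, -16.0)
    assert got == pytest.approx(expected, abs=1e-9)


def test_constant_waveform_component_values():
    c = 2.5
    t_erp = _target_erp(lambda t: np.full_like(t, c))
    s_erp = _saccade_erp(lambda t: np.full_like(t, c))
    assert E.measure_component(t_erp, "pretarget_neg_sw", "E61").value_uv == pytest.approx(0.0, abs=1e-12)
    assert E.measure_component(s_erp, "spike", "E61").value_uv == pytest.approx(0.0, abs=1e-12)
    assert E.measure_component(s_erp, "presaccadic_pos_sw", "E61").value_uv == pytest.approx(c, abs=1e-12)


def test_component_alignment_mismatch_raises():
    erp = _saccade_erp(lambda t: np.zeros_like(t))
    with pytest.raises(AlignmentError):
        E.measure_component(erp, "pretarget_neg_sw", "E61")


def test_group_scope_equals_mean_of_member_channels(montage):
    times = np.arange(-300.0, 101.0, 4.0)
    rng = np.random.default_rng(3)
    data = rng.normal(size=(len(montage.channels), times.size))
    erp = E.ERPWave({}, data, times, list(montage.channels), "saccade", 1)
    members, member_data, mean_wave = E.virtual_group_values(erp, montage, "OccipitalZ")
    assert members == ["E72", "E77", "E76"]
    np.testing.assert_allclose(mean_wave, member_data.mean(axis=0))
    group_val = E.measure_component(erp, "presaccadic_pos_sw", "OccipitalZ", montage).value_uv
    per_ch = [E.measure_component(erp, "presaccadic_pos_sw", ch).value_uv for ch in members]
    assert group_val == pytest.approx(np.mean(per_ch), abs=1e-12)


def test_unknown_group_raises(montage):
    erp = _saccade_erp(lambda t: np.zeros_like(t))
    with pytest.raises(KeyError):
        E.virtual_group_values(erp, montage, "NoSuchGroup")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(min_value=-50.0, max_value=50.0))
def test_window_mean_is_linear_in_constant_shifts(c):
    times = np.arange(-300.0, 101.0, 4.0)
    rng = np.random.default_rng(4)
    x = rng.normal(size=times.size)
    base = E.window_mean(x, times, (-50.0, -20.0))
    shifted = E.window_mean(x + c, times, (-50.0, -20.0))
    assert shifted == pytest.approx(base + c, abs=1e-9)


# ---------------------------------------------------------------------------
# Saccade detection
# ---------------------------------------------------------------------------

def test_detect_saccade_step_and_ramp():
    times = np.arange(0.0, 1000.0, 4.0)
    step = np.where(times >= 480.0, 50.0, 0.0)
    assert E.detect_saccade_onset(step, times, 25.0) == 480.0
    ramp = np.clip((times - 400.0) / 100.0, 0, 1) * 50.0
    assert E.detect_saccade_onset(ramp, times, 25.0) == 452.0
    assert E.detect_saccade_onset(np.zeros_like(times), times, 25.0) is None


def test_detect_saccade_requires_finite_trace():
    times = np.arange(0.0, 100.0, 4.0)
    trace = np.zeros_like(times)
    trace[3] = np.nan
    with pytest.raises(InvalidSignalError):
        E.detect_saccade_onset(trace, times, 25.0)


def test_detect_saccade_ignores_brief_blips():
    times = np.arange(0.0, 1000.0, 4.0)
    trace = np.zeros_like(times)
    trace[50] = 100.0  # single-sample artifact
    trace[times >= 600.0] = 50.0
    assert E.detect_saccade_onset(trace, times, 25.0, min_duration_ms=12.0) == 600.0
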