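"""Spike detection and causal-window binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dmsdecode as d
from dmsdecode.task import TrialRecord


def _events(rows):
    return pd.DataFrame(rows, columns=["trial_id", "channel", "spike_time_ms"])


def _trial(tid=0, rt=600.0):
    return TrialRecord(tid, 0, 0, "match", "forward", True, rt)


# ---------------------------------------------------------------------------
# detect_spikes


def _naive_detect(x, mult, dead_samples):
    thresh = mult * np.std(x)
    out = []
    last = -np.inf
    for i, v in enumerate(x):
        if abs(v) >= thresh and i - last > dead_samples:
            out.append(i)
            last = i
    return np.array(out)


def test_detect_zero_variance_signal_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        d.detect_spikes(np.full(1000, 2.0))


def test_detect_injected_deflections(rng):
    x = rng.standard_normal(25_000)  # 1 s at 25 kHz
    inject = np.arange(1000, 21_000, 2000)
    x[inject] = 8.0
    times = d.detect_spikes(x, threshold_multiplier=4.0, dead_time_ms=1.0)
    samples = np.round(times * 25.0).astype(int)
    assert len(times) >= len(inject)
    for i in inject:
        assert np.min(np.abs(samples - i)) <= 1
    # False positives bounded by the Gaussian tail: P(|z|>4) per sample.
    expected_fp = 2 * 25_000 * 3.2e-5
    assert len(times) - len(inject) <= expected_fp * 5 + 3


def test_detect_matches_naive_loop(rng):
    x = rng.standard_normal(5000)
    x[rng.integers(0, 5000, 20)] += 6.0
    ours = np.round(d.detect_spikes(x, 4.0, dead_time_ms=0.2) * 25.0).astype(int)
    theirs = _naive_detect(x, 4.0, dead_samples=0.2 * 25.0)
    np.testing.assert_array_equal(ours, theirs)


def test_detect_dead_time_merges_adjacent_crossings():
    x = np.zeros(2500)
    x[::50] = 0.01  # nonzero variance
    x[100] = x[110] = 10.0  # 0.4 ms apart at 25 kHz
    times = d.detect_spikes(x, 4.0, dead_time_ms=1.0)
    assert len(times) == 1
    with pytest.raises(ValueError, match="dead_time"):
        d.detect_spikes(x, 4.0, dead_time_ms=0.0)


# ---------------------------------------------------------------------------
# bin_firing_rates


def test_single_spike_bookkeeping_halfopen_window():
    """A spike at 2700 counts in windows labeled [2700, 2850) only."""
    events = _events([(0, 0, 2700.0)])
    tensor = d.bin_firing_rates(
        events, [_trial()], window_ms=150.0, step_ms=50.0,
        t_range_ms=(2500.0, 2900.0), n_channels=1,
    )
    rate = {t: v for t, v in zip(tensor.bin_times_ms, tensor.values[0, 0])}
    for t in (2700.0, 2750.0, 2800.0):
        assert rate[t] == pytest.approx(1000.0 / 150.0)
    assert rate[2650.0] == 0.0
    assert rate[2850.0] == 0.0  # half-open (t−w, t] excludes a spike at t−w


def test_empty_event_table_gives_zero_tensor():
    tensor = d.bin_firing_rates(
        _events([]), [_trial(0), _trial(1)], t_range_ms=(0.0, 1000.0), n_channels=3
    )
    assert tensor.values.shape == (2, 3, len(tensor.bin_times_ms))
    assert not tensor.values.any()


def test_poisson_channel_mean_rate(rng):
    """Homogeneous 20 sp/s events: binned rates average to 20."""
    rows = []
    for tid in range(500):
        n = rng.poisson(20.0 * 3.0)
        for t in np.sort(rng.uniform(0, 3000.0, n)):
            rows.append((tid, 0, t))
    trials = [_trial(tid) for tid in range(500)]
    tensor = d.bin_firing_rates(_events(rows), trials, t_range_ms=(0.0, 3000.0),
                                n_channels=1)
    mean = tensor.values.mean()
    se = np.sqrt(20.0 / (0.150 * 500 * tensor.n_bins / 3))  # generous
    assert abs(mean - 20.0) < 4 * se


def test_count_conservation_with_disjoint_bins(rng):
    times = rng.uniform(0.0, 2000.0, 400)
    rows = [(0, 0, t) for t in times]
    tensor = d.bin_firing_rates(
        _events(rows), [_trial()], window_ms=100.0, step_ms=100.0,
        t_range_ms=(0.0, 2000.0), n_channels=1,
    )
    total = tensor.values.sum() * 100.0 / 1000.0
    assert total == np.sum((times > 0.0) & (times <= 2000.0))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.floats(-500.0, 500.0), st.integers(0, 2**31 - 1))
def test_shift_equivariance(delta, seed):
    rng = np.random.default_rng(seed)
    times = rng.uniform(100.0, 900.0, 50)
    base = d.bin_firing_rates(
        _events([(0, 0, t) for t in times]), [_trial()],
        window_ms=150.0, step_ms=50.0, t_range_ms=(0.0, 1000.0), n_channels=1,
    )
    shifted = d.bin_firing_rates(
        _events([(0, 0, t + delta) for t in times]), [_trial(rt=2000.0)],
        window_ms=150.0, step_ms=50.0, t_range_ms=(0.0 + delta, 1000.0 + delta),
        n_channels=1,
    )
    np.testing.assert_allclose(base.values, shifted.values, atol=1e-12)


def test_causality_of_binning(rng):
    times = list(rng.uniform(0.0, 1500.0, 100))
    kw = dict(window_ms=150.0, step_ms=50.0, t_range_ms=(0.0, 1000.0), n_channels=1)
    before = d.bin_firing_rates(_events([(0, 0, t) for t in times]), [_trial()], **kw)
    extra = times + [1001.0, 1100.0, 1400.0]  # all strictly after the last bin
    after = d.bin_firing_rates(_events([(0, 0, t) for t in extra]), [_trial()], **kw)
    np.testing.assert_array_equal(before.values, after.values)


def test_bad_bin_parameters_rejected():
    with pytest.raises(ValueError):
        d.bin_firing_rates(_events([]), [_trial()], window_ms=0.0)
    with pytest.raises(ValueError):
        d.bin_firing_rates(_events([]), [_trial()], step_ms=-1.0)
    with pytest.raises(ValueError, match="t_range"):
        d.bin_firing_rates(_events([]), [_trial()], t_range_ms=(0.0, 100.0))


# ---------------------------------------------------------------------------
# response alignment


def test_align_to_response_definition():
    events = _events([(0, 0, 3100.0)])
    out = d.align_to_response(events, [_trial(rt=600.0)])
    assert out.spike_time_ms.iloc[0] == pytest.approx(0.0)


def test_equal_rts_shift_equivalence():
    rows = [(0, 0, 2600.0), (0, 0, 2800.0), (1, 0, 2700.0)]
    trials = [_trial(0, rt=500.0), _trial(1, rt=500.0)]
    stim = d.bin_firing_rates(_events(rows), trials, t_range_ms=(2400.0, 2900.0),
                              n_channels=1)
    resp = d.bin_firing_rates(_events(rows), trials, alignment="response_onset",
                              t_range_ms=(2400.0 - 3000.0, 2900.0 - 3000.0),
                              n_channels=1)
    np.testing.assert_allclose(stim.values, resp.values)


def test_response_alignment_requires_rt():
    trials = pd.DataFrame(
        [(0, 0, 0, "match", "forward", True, np.nan)],
        columns=["trial_id", "sample_stim", "test_stim", "trial_type", "choice",
                 "correct", "rt_ms"],
    )
    with pytest.raises(ValueError, match="trial 0"):
        d.align_to_response(_events([(0, 0, 100.0)]), trials)


def test_response_aligned_generator_session_bounds():
    """After response alignment, 0 marks each trial's response: no spike can
    occur later than the post-response recording tail or the end of the
    longest possible test epoch, and fixation spikes sit far in the past."""
    cfg = d.default_config(n_trials=100, seed=21, error_rate=0.0)
    events, trials = d.generate_session(cfg)
    out = d.align_to_response(events, trials)
    assert out.spike_time_ms.max() <= max(cfg.post_response_ms, cfg.test_max_ms) + 1e-6
    assert out.spike_time_ms.min() >= -(cfg.test_onset_ms + max(t.rt_ms for t in trials))
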