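"""Time-resolved decoding curves: chance behavior, interpolation, statistics."""

import numpy as np
import pytest

import dmsdecode as d
from dmsdecode.task import trials_to_frame


def _curve(per_session, times=None, chance=1 / 3, step=50.0):
    per_session = np.atleast_2d(per_session)
    if times is None:
        times = 2500.0 + step * np.arange(per_session.shape[1])
    return d.DecodingCurve(
        times_ms=np.asarray(times, float),
        per_session_accuracy=per_session,
        chance_level=chance,
        window_ms=150.0,
        step_ms=step,
    )


def test_no_signal_curve_is_flat_at_chance():
    cfg = d.default_config(
        n_trials=180, seed=31, stim_gain=np.zeros((32, 3)), decision_gain=0.0
    )
    events, trials = d.generate_session(cfg)
    tf = trials_to_frame(trials)
    tfc = tf[tf.correct].reset_index(drop=True)
    tensor = d.bin_firing_rates(events, tfc, t_range_ms=(2400.0, 2900.0))
    curve = d.time_resolved_decode(tensor, tfc.test_stim.to_numpy(), seed=0)
    assert np.all(np.abs(curve.mean_accuracy - curve.chance_level) < 0.12)
    assert abs(curve.mean_accuracy.mean() - curve.chance_level) < 0.05


def test_decodability_confined_to_stimulus_epoch():
    """Sample identity is readable only where causal windows overlap the
    (latency-shifted) sample epoch."""
    cfg = d.default_config(n_trials=300, seed=32, decision_gain=0.0)
    events, trials = d.generate_session(cfg)
    tf = trials_to_frame(trials)
    tensor = d.bin_firing_rates(events, tf, t_range_ms=(200.0, 1400.0))
    curve = d.time_resolved_decode(tensor, tf.sample_stim.to_numpy(), seed=0)
    acc = dict(zip(curve.times_ms, curve.mean_accuracy))
    assert acc[500.0] < 0.45  # window (350, 500]: before sample onset
    assert acc[800.0] > 0.8  # fully inside the driven sample epoch
    assert acc[1400.0] < 0.5  # window (1250, 1400]: tuning off after 1050


def test_stronger_tuning_decodes_no_worse():
    curves = []
    for scale in (0.4, 1.6):
        base = d.default_config(n_trials=200, seed=33)
        cfg = d.default_config(
            n_trials=200, seed=33, stim_gain=base.stim_gain * scale,
            decision_direction=base.decision_direction,
        )
        events, trials = d.generate_session(cfg)
        tf = trials_to_frame(trials)
        tensor = d.bin_firing_rates(events, tf, t_range_ms=(2500.0, 3000.0))
        curves.append(d.time_resolved_decode(tensor, tf.test_stim.to_numpy(), seed=0))
    weak, strong = curves
    frac = np.mean(strong.mean_accuracy >= weak.mean_accuracy)
    assert frac > 0.5


def test_interpolation_preserves_knots_and_constants():
    const = _curve(np.full((2, 6), 0.8))
    fine = d.interpolate_curve(const, 2.0)
    assert fine.interpolated
    np.testing.assert_allclose(fine.per_session_accuracy, 0.8, atol=1e-12)

    wiggly = _curve(np.array([[0.3, 0.9, 0.5, 0.7, 0.4, 0.65]]))
    fine = d.interpolate_curve(wiggly, 2.0)
    for t, v in zip(wiggly.times_ms, wiggly.per_session_accuracy[0]):
        idx = np.argmin(np.abs(fine.times_ms - t))
        assert fine.per_session_accuracy[0, idx] == pytest.approx(v, abs=1e-10)


def test_natural_spline_of_linear_data_is_linear():
    times = 2500.0 + 50.0 * np.arange(6)
    vals = 0.4 + 0.001 * (times - times[0])
    fine = d.interpolate_curve(_curve(vals[None, :], times=times), 1.0)
    expected = 0.4 + 0.001 * (fine.times_ms - times[0])
    np.testing.assert_allclose(fine.per_session_accuracy[0], expected, atol=1e-9)


def test_interpolation_needs_four_points():
    with pytest.raises(ValueError, match="4 time points"):
        d.interpolate_curve(_curve(np.full((1, 3), 0.5)), 2.0)


def test_vs_chance_ttest_matches_hand_computation():
    vals = np.array([0.9, 0.92, 0.94, 0.93, 0.95, 0.91])
    curve = _curve(np.tile(vals[:, None], (1, 4)))
    t_stat, p, n = d.curve_vs_chance_test(curve, 2600.0)
    diffs = vals - 1 / 3
    t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(vals)))
    assert t_stat == pytest.approx(t_hand, rel=1e-12)
    assert n == 6 and p < 0.01


def test_vs_chance_ttest_degenerate_cases():
    flat = _curve(np.full((4, 5), 1 / 3))
    t_stat, p, _ = d.curve_vs_chance_test(flat, 2550.0)
    assert (t_stat, p) == (0.0, 1.0)
    with pytest.raises(ValueError, match="2 sessions"):
        d.curve_vs_chance_test(_curve(np.full((1, 5), 0.5)), 2550.0)


def test_latency_trivial_cases():
    flat = _curve(np.full((1, 10), 0.5), chance=0.5)
    assert d.latency_of_chance_crossing(flat) is None

    vals = np.where(2500.0 + 50.0 * np.arange(10) >= 2650.0, 0.9, 0.5)
    step_curve = _curve(vals[None, :], chance=0.5)
    assert d.latency_of_chance_crossing(step_curve) == pytest.approx(150.0)


def test_latency_ignores_short_blips():
    vals = np.full(20, 0.48)
    vals[3] = 0.6  # single 10-ms bin above chance
    vals[10:] = 0.8  # true, persistent crossing
    times = 2500.0 + 10.0 * np.arange(20)
    curve = _curve(vals[None, :], times=times, chance=0.5, step=10.0)
    lat = d.latency_of_chance_crossing(curve, persistence_ms=50.0)
    assert lat == pytest.approx(100.0)


def test_fold_count_robustness(correct_tensor):
    """10- vs 20-fold CV agree within 3 percentage points on a strong bin."""
    cfg, tensor, tfc = correct_tensor
    X = tensor.at_time(2700.0)
    y = tfc.test_stim.to_numpy()
    a10, _ = d.crossval_accuracy(X, y, n_folds=10, seed=0)
    a20, _ = d.crossval_accuracy(X, y, n_folds=20, seed=0)
    assert abs(a10 - a20) < 0.03


def test_ten_ms_step_supersets_fifty_ms_grid(session600):
    cfg, events, tf = session600
    tfc = tf[tf.correct].reset_index(drop=True)
    kw = dict(t_range_ms=(2500.0, 2800.0), n_channels=cfg.n_channels)
    coarse = d.bin_firing_rates(events, tfc, step_ms=50.0, **kw)
    fine = d.bin_firing_rates(events, tfc, step_ms=10.0, **kw)
    shared = np.intersect1d(coarse.bin_times_ms, fine.bin_times_ms)
    assert len(shared) == len(coarse.bin_times_ms)
    y = tfc.test_stim.to_numpy()
    for t in shared[:3]:
        ac, _ = d.crossval_accuracy(coarse.at_time(t), y, seed=0)
        af, _ = d.crossval_accuracy(fine.at_time(t), y, seed=0)
        assert ac == pytest.approx(af, abs=1e-12)  # identical rate vectors


def test_decoder_model_results_roundtrip(session600):
    cfg, events, tf = session600
    decoder = d.PopulationDecoder.from_session(
        events, tf, target="stimulus", t_range_ms=(2550.0, 2800.0),
        n_channels=cfg.n_channels,
    )
    curve = decoder.fit(seed=0)
    assert curve.chance_level == pytest.approx(1 / 3)
    assert "peak accuracy" in curve.summary()
    frame = curve.to_frame()
    assert set(frame.columns) == {"session", "time_ms", "accuracy"}
    # refitting with the same seed reproduces the curve
    np.testing.assert_array_equal(
        curve.per_session_accuracy, decoder.fit(seed=0).per_session_accuracy
    )
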