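"""Discriminant subspaces: closed forms, optimality, geometry recovery."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

import dmsdecode as d
from dmsdecode.task import trials_to_frame


def test_two_class_identity_covariance_closed_form():
    """With isotropic within-class scatter the discriminant is the mean
    difference direction."""
    offsets = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    m0, m1 = np.array([0.0, 0.0]), np.array([3.0, 4.0])
    X = np.vstack([m0 + offsets, m1 + offsets])
    y = np.repeat([0, 1], 4)
    W = d.fit_discriminant_subspace(X, y, shrinkage=0.0)
    expected = (m1 - m0) / np.linalg.norm(m1 - m0)
    np.testing.assert_allclose(np.abs(W[:, 0]), np.abs(expected), atol=1e-10)


@pytest.mark.parametrize("k", [2, 3, 4])
def test_dimension_law(k, rng):
    X = rng.standard_normal((30 * k, 6))
    y = np.repeat(np.arange(k), 30)
    X += y[:, None] * 0.5
    W = d.fit_discriminant_subspace(X, y)
    assert W.shape == (6, k - 1)
    np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-12)
    # sign convention: largest-magnitude entry positive
    for col in W.T:
        assert col[np.abs(col).argmax()] > 0


def test_leading_direction_beats_random_directions(rng):
    """No random unit direction achieves a higher between/within scatter
    ratio than the leading fitted discriminant."""
    X = rng.standard_normal((45, 4))
    y = np.repeat([0, 1, 2], 15)
    X[y == 1, 0] += 2.0
    X[y == 2, 1] += 1.0
    W = d.fit_discriminant_subspace(X, y, shrinkage=0.0)

    grand = X.mean(0)
    sw = np.zeros((4, 4))
    sb = np.zeros((4, 4))
    for k in range(3):
        g = X[y == k]
        dm = g - g.mean(0)
        sw += dm.T @ dm
        off = g.mean(0) - grand
        sb += len(g) * np.outer(off, off)

    def ratio(v):
        return (v @ sb @ v) / (v @ sw @ v)

    best = ratio(W[:, 0])
    dirs = rng.standard_normal((10_000, 4))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    assert max(ratio(v) for v in dirs) <= best + 1e-9


def test_principal_angles_trivial_geometry():
    e1 = np.array([[1.0], [0.0], [0.0]])
    e2 = np.array([[0.0], [1.0], [0.0]])
    assert d.subspace_principal_angles(e1, e1)[0] == pytest.approx(0.0, abs=1e-8)
    assert d.subspace_principal_angles(e1, e2)[0] == pytest.approx(90.0)
    plane = np.eye(3)[:, :2]
    angs = d.subspace_principal_angles(plane, plane)
    np.testing.assert_allclose(angs, [0.0, 0.0], atol=1e-8)
    with pytest.raises(ValueError, match="full column rank"):
        d.subspace_principal_angles(np.zeros((3, 1)), e1)


def test_rotation_equivariance(rng):
    """Rotating channel space leaves angles and silhouettes invariant."""
    X = rng.standard_normal((120, 5))
    y_stim = np.repeat([0, 1, 2], 40)
    X[y_stim == 1, 0] += 3.0
    X[y_stim == 2, 1] += 3.0
    y_dec = np.tile(np.repeat([0, 1], 20), 3)
    X[:, 4] += np.where(y_dec == 0, 1.5, -1.5)

    q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
    Xr = X @ q.T

    # shrinkage 0: the diagonal shrinkage target is basis-dependent, so only
    # the unregularized fit is exactly rotation-equivariant
    Ws, Wr = (d.fit_discriminant_subspace(Z, y_stim, shrinkage=0.0) for Z in (X, Xr))
    As, Ar = (d.fit_discriminant_subspace(Z, y_dec, shrinkage=0.0) for Z in (X, Xr))
    ang = d.subspace_principal_angles(As, Ws)[0]
    ang_r = d.subspace_principal_angles(Ar, Wr)[0]
    assert ang == pytest.approx(ang_r, abs=1e-6)
    sil = d.class_separation_score(X @ Ws, y_stim)
    sil_r = d.class_separation_score(Xr @ Wr, y_stim)
    assert sil == pytest.approx(sil_r, abs=1e-6)
    # rotated projection spans the rotated original span
    assert d.subspace_principal_angles(q @ Ws, Wr)[-1] < 1e-4


def test_silhouette_trivial_and_oracle(rng):
    tight = np.vstack([rng.normal(0, 0.01, (20, 2)), rng.normal(50, 0.01, (20, 2))])
    labels = np.repeat([0, 1], 20)
    assert d.class_separation_score(tight, labels) > 0.99
    blob = rng.standard_normal((40, 2))
    assert abs(d.class_separation_score(blob, labels)) < 0.15
    # oracle agreement with scikit-learn on 20 random points
    pts = rng.standard_normal((20, 3))
    labs = rng.integers(0, 3, 20)
    while np.unique(labs, return_counts=True)[1].min() < 2:
        labs = rng.integers(0, 3, 20)
    assert d.class_separation_score(pts, labs) == pytest.approx(
        silhouette_score(pts, labs), abs=1e-12
    )


def test_silhouette_singleton_class_scored_zero(rng):
    pts = rng.standard_normal((5, 2))
    labs = np.array([0, 0, 0, 0, 1])
    with pytest.warns(RuntimeWarning, match="singleton"):
        s = d.class_separation_score(pts, labs)
    assert -1.0 <= s <= 1.0


def test_build_subspace_model_on_generator(correct_tensor):
    cfg, tensor, tfc = correct_tensor
    model = d.build_subspace_model(tensor, tfc, t_ref_ms=2700.0)
    assert model.stim_projection.shape == (cfg.n_channels, 2)
    assert model.decision_projection.shape == (cfg.n_channels, 1)
    pts = model.project(tensor.at_time(2700.0))
    assert pts.shape == (tensor.n_trials, 3)
    # stimulus clustering strong, decision overlap complete (pre-asymptotic
    # choice signal contributes little at 2700 in the stimulus plane)
    assert d.class_separation_score(pts[:, :2], tfc.test_stim.to_numpy()) > 0.4
    assert abs(d.class_separation_score(pts[:, :2], tfc.trial_type.to_numpy())) < 0.1
    assert "principal angle" in model.summary()


def test_subspace_model_warns_without_decision_signal():
    cfg = d.default_config(n_trials=240, seed=41, decision_gain=0.0)
    events, trials = d.generate_session(cfg)
    tf = trials_to_frame(trials)
    tfc = tf[tf.correct].reset_index(drop=True)
    tensor = d.bin_firing_rates(events, tfc, t_range_ms=(2300.0, 3000.0))
    with pytest.warns(RuntimeWarning, match="near chance"):
        d.build_subspace_model(tensor, tfc, t_ref_ms=2900.0)


def test_off_grid_reference_time_warns(correct_tensor):
    cfg, tensor, tfc = correct_tensor
    with pytest.warns(RuntimeWarning, match="nearest bin"):
        model = d.build_subspace_model(tensor, tfc, t_ref_ms=2712.0)
    assert model.t_ref_ms == 2700.0


def test_project_trajectories_shapes_and_zero_input(correct_tensor):
    cfg, tensor, tfc = correct_tensor
    model = d.build_subspace_model(tensor, tfc, t_ref_ms=2700.0)
    traj = d.project_trajectories(tensor, model)
    assert traj.shape == (tensor.n_trials, tensor.n_bins, 3)
    zero = d.RateTensor(
        values=np.zeros((2, cfg.n_channels, 4)),
        bin_times_ms=np.array([2550.0, 2600.0, 2650.0, 2700.0]),
        window_ms=150.0, step_ms=50.0, alignment="stimulus_onset",
        trial_index=np.array([0, 1]),
    )
    np.testing.assert_array_equal(d.project_trajectories(zero, model), 0.0)
    # projecting the t_ref vectors reproduces the fit-time points
    idx = tensor.bin_at(2700.0)
    np.testing.assert_allclose(
        traj[:, idx, :], model.project(tensor.at_time(2700.0)), atol=1e-12
    )


def test_trajectories_deflect_along_decision_axis_after_latency(correct_tensor):
    """Forward vs backward trajectories separate along the decision axis only
    once the choice signal is on (onset 2650 ms in the standard config)."""
    from scipy.stats import ttest_ind

    cfg, tensor, tfc = correct_tensor
    model = d.build_subspace_model(tensor, tfc, t_ref_ms=2900.0)
    traj = d.project_trajectories(tensor, model)
    fwd = (tfc.choice == "forward").to_numpy()

    def pval(t_ms):
        b = tensor.bin_at(t_ms)
        return ttest_ind(traj[fwd, b, 2], traj[~fwd, b, 2]).pvalue

    assert pval(2600.0) > 0.01  # pre-onset: no separation
    assert pval(2950.0) < 1e-6  # signal fully on


def test_recovered_angle_monotone_in_injected_angle():
    recovered = []
    for ang in (30.0, 60.0, 90.0):
        comps = []
        for seed in (61, 62):
            cfg = d.default_config(n_trials=500, seed=seed, decision_angle_deg=ang)
            events, trials = d.generate_session(cfg)
            tf = trials_to_frame(trials)
            tensor = d.bin_firing_rates(events, tf, t_range_ms=(2300.0, 3000.0))
            comps.append((tensor, tf))
        recovered.append(
            d.estimate_decision_angle([c[0] for c in comps], [c[1] for c in comps])
        )
    assert recovered[0] < recovered[1] < recovered[2]


def test_condition_average_trajectories_table(correct_tensor):
    cfg, tensor, tfc = correct_tensor
    model = d.build_subspace_model(tensor, tfc, t_ref_ms=2700.0)
    traj = d.project_trajectories(tensor, model)
    table = d.condition_average_trajectories(traj, tfc, tensor.trial_index)
    # 3 stimuli × 2 choices × bins × 3 axes rows (correct trials only)
    assert set(table.columns) == {"test_stim", "choice", "bin", "axis", "value"}
    assert len(table) == 6 * tensor.n_bins * 3
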