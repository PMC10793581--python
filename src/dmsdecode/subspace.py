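"""Stimulus and decision subspaces of the population activity.

LDA doubles as a supervised dimensionality reduction: for a k-class labeling
it yields a (k−1)-dimensional projection maximizing between-class relative to
within-class scatter (the leading generalized eigenvectors of (S_b, S_w)).
Fitting the projection at a single reference time with stimulus labels gives
a 2-D stimulus subspace (3 stimuli) and with match/nonmatch labels a 1-D
decision axis.  Projecting the rate trajectories into the joint 3-D space
shows when the population separates by stimulus and when it deflects along
the decision axis; principal angles between the two subspaces quantify their
orthogonality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import cdist

from .lda import crossval_accuracy
from .preprocess import RateTensor
from .task import TrialRecord, trials_to_frame

__all__ = [
    "SubspaceModel",
    "fit_discriminant_subspace",
    "build_subspace_model",
    "project_trajectories",
    "condition_average_trajectories",
    "decision_angle_components",
    "estimate_decision_angle",
    "subspace_principal_angles",
    "class_separation_score",
]


def fit_discriminant_subspace(
    X: np.ndarray, y: np.ndarray, shrinkage: float = 0.1
) -> np.ndarray:
    """Discriminant projection matrix, channels × (n_classes − 1).

    Columns are the leading generalized eigenvectors of the between-class
    scatter against the (shrinkage-regularized) within-class scatter, ordered
    by decreasing eigenvalue, scaled to unit Euclidean norm, with the sign
    fixed so each column's largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")

    n, p = X.shape
    grand = X.mean(axis=0)
    means = np.vstack([X[y == lab].mean(axis=0) for lab in labels])
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for lab, m, c in zip(labels, means, counts):
        d = X[y == lab] - m
        sw += d.T @ d
        offset = m - grand
        sb += c * np.outer(offset, offset)
    sw /= n - k
    sb /= n
    sw = (1.0 - shrinkage) * sw + shrinkage * np.diag(np.diag(sw))

    try:
        eigvals, eigvecs = linalg.eigh(sb, sw)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"generalized eigenproblem failed ({exc}); increase shrinkage"
        ) from None
    order = np.argsort(eigvals)[::-1][: k - 1]
    W = eigvecs[:, order]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    # Sign convention: largest-magnitude entry of each column positive.
    flip = np.sign(W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])])
    return W * flip


@dataclass(frozen=True)
class SubspaceModel:
    """Stimulus (2-D) and decision (1-D) projections fit at one time point."""

    stim_projection: np.ndarray  # channels × (n_stimuli − 1)
    decision_projection: np.ndarray  # channels × 1
    t_ref_ms: float
    fit_labels: dict
    shrinkage: float

    def __post_init__(self) -> None:
        sp = np.atleast_2d(np.asarray(self.stim_projection, dtype=float))
        dp = np.asarray(self.decision_projection, dtype=float).reshape(-1, 1)
        if np.linalg.matrix_rank(sp) < sp.shape[1]:
            raise ValueError("stimulus projection is rank deficient")
        if not np.any(dp):
            raise ValueError("decision projection is zero")
        object.__setattr__(self, "stim_projection", sp)
        object.__setattr__(self, "decision_projection", dp)

    @property
    def n_channels(self) -> int:
        return self.stim_projection.shape[0]

    @property
    def joint_projection(self) -> np.ndarray:
        """Channels × 3 matrix: [stim axis 1, stim axis 2, decision axis]."""
        return np.hstack([self.stim_projection, self.decision_projection])

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project rate vectors (… × channels) into the joint 3-D space."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_channels:
            raise ValueError(
                f"last axis has {X.shape[-1]} channels, model expects {self.n_channels}"
            )
        return X @ self.joint_projection

    def principal_angles_deg(self) -> np.ndarray:
        """Principal angle(s) between the decision axis and the stimulus span."""
        return subspace_principal_angles(self.decision_projection, self.stim_projection)

    def summary(self) -> str:
        ang = self.principal_angles_deg()
        lines = [
            "Task subspaces (discriminant projections)",
            "=" * 45,
            f"reference time:     {self.t_ref_ms:.0f} ms",
            f"stimulus subspace:  {self.stim_projection.shape[1]}-D "
            f"(labels: {self.fit_labels.get('stimulus')})",
            f"decision subspace:  {self.decision_projection.shape[1]}-D "
            f"(labels: {self.fit_labels.get('decision')})",
            f"shrinkage:          {self.shrinkage:g}",
            f"decision↔stimulus principal angle: {ang[0]:.1f}°",
        ]
        return "\n".join(lines)


def build_subspace_model(
    tensor: RateTensor,
    trials: list[TrialRecord] | pd.DataFrame,
    t_ref_ms: float = 2700.0,
    shrinkage: float = 0.1,
    correct_only: bool = True,
    seed: int = 0,
) -> SubspaceModel:
    """Fit both projections from the rate vectors at the reference time.

    The stimulus projection uses test-stimulus identity labels, the decision
    projection match/nonmatch labels, both from the same (correct-trial) rate
    vectors.  If the requested time is off the bin grid the nearest bin is
    used with a warning; if the decision labels are barely separable a
    warning flags that the decision axis is fit to noise.
    """
    tf = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    tf = tf.set_index("trial_id").loc[tensor.trial_index].reset_index()
    idx = tensor.bin_at(t_ref_ms)
    actual = tensor.bin_times_ms[idx]
    if abs(actual - t_ref_ms) > 1e-6:
        warnings.warn(
            f"t_ref {t_ref_ms:g} ms is not on the bin grid; using nearest bin "
            f"at {actual:g} ms",
            RuntimeWarning,
            stacklevel=2,
        )
    mask = tf["correct"].to_numpy(dtype=bool) if correct_only else np.ones(len(tf), bool)
    X = tensor.values[mask, :, idx]
    y_stim = tf.loc[mask, "test_stim"].to_numpy()
    y_dec = tf.loc[mask, "trial_type"].to_numpy()

    stim_proj = fit_discriminant_subspace(X, y_stim, shrinkage=shrinkage)
    dec_proj = fit_discriminant_subspace(X, y_dec, shrinkage=shrinkage)

    acc, _ = crossval_accuracy(X, y_dec, n_folds=5, seed=seed, shrinkage=shrinkage)
    se = np.sqrt(0.25 / len(y_dec))
    if acc < 0.5 + 2 * se:
        warnings.warn(
            f"match/nonmatch separability at t_ref is near chance "
            f"(CV accuracy {acc:.3f}); the decision axis may reflect noise",
            RuntimeWarning,
            stacklevel=2,
        )
    return SubspaceModel(
        stim_projection=stim_proj,
        decision_projection=dec_proj,
        t_ref_ms=float(actual),
        fit_labels={"stimulus": "test_stim", "decision": "trial_type"},
        shrinkage=shrinkage,
    )


def project_trajectories(tensor: RateTensor, model: SubspaceModel) -> np.ndarray:
    """Trials × bins × 3 trajectories in [stim 1, stim 2, decision] space."""
    if tensor.n_channels != model.n_channels:
        raise ValueError(
            f"tensor has {tensor.n_channels} channels, model expects {model.n_channels}"
        )
    # values: (trials, channels, bins) → (trials, bins, channels) → project
    return np.einsum("tcb,cd->tbd", tensor.values, model.joint_projection)


def condition_average_trajectories(
    trajectories: np.ndarray,
    trials: list[TrialRecord] | pd.DataFrame,
    trial_index: np.ndarray,
    by: tuple[str, ...] = ("test_stim", "choice"),
) -> pd.DataFrame:
    """Average trajectories within conditions (default stimulus × choice).

    Returns a long-form table with one row per (condition, bin, axis).
    """
    tf = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    tf = tf.set_index("trial_id").loc[trial_index].reset_index()
    rows = []
    for cond, grp in tf.groupby(list(by), sort=True):
        mean_traj = trajectories[grp.index.to_numpy()].mean(axis=0)  # bins × 3
        for b in range(mean_traj.shape[0]):
            for d in range(mean_traj.shape[1]):
                rows.append((*cond, b, d, mean_traj[b, d]))
    return pd.DataFrame(rows, columns=[*by, "bin", "axis", "value"])


def decision_angle_components(
    tensor: RateTensor,
    trials: list[TrialRecord] | pd.DataFrame,
    t_window_ms: tuple[float, float] = (2750.0, 2900.0),
    rt_exclude_ms: float = 400.0,
    shrinkage: float = 0.1,
) -> tuple[float, float]:
    """Noise-corrected (in-span energy, total energy) of the decision axis.

    Estimating the angle between the decision axis and the stimulus span from
    single-trial rates is attenuated two ways: sampling noise inflates the
    norm of the estimated axis (biasing the angle toward that of a random
    vector), and the choice-signal variance sits inside the stimulus fit's
    within-class scatter (repelling the fitted span from the decision
    direction).  Both are corrected here:

    * rate vectors are averaged over the bins in ``t_window_ms`` (test epoch,
      choice signal fully on) to raise the integration time;
    * the within-class scatter for the stimulus-span fit is pooled within
      (stimulus × trial-type) cells, so neither signal contaminates it;
    * the decision axis is the cell-balanced match−nonmatch mean difference,
      and its estimated sampling covariance is subtracted from both the
      in-span energy ``|QᵀΔ|²`` and the total energy ``|Δ|²``
      (a classical attenuation correction).

    Returns the corrected ``(in_span, total)`` energies; ``arccos(sqrt(
    in_span/total))`` is the angle.  Components from several sessions can be
    summed before taking the ratio, which stabilizes angles near 90° where
    the corrected in-span energy fluctuates around zero.
    """
    tf = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    tf = tf.set_index("trial_id").loc[tensor.trial_index].reset_index()
    keep = (
        tf["correct"].to_numpy(dtype=bool)
        & (tf["rt_ms"].to_numpy(dtype=float) >= rt_exclude_ms)
    )
    sel = (tensor.bin_times_ms >= t_window_ms[0]) & (tensor.bin_times_ms <= t_window_ms[1])
    if not sel.any():
        raise ValueError(f"no bins inside t_window_ms {t_window_ms}")
    X = tensor.values[keep][:, :, sel].mean(axis=2)
    y_stim = tf.loc[keep, "test_stim"].to_numpy()
    y_dec = tf.loc[keep, "trial_type"].to_numpy()

    stims = np.unique(y_stim)
    decs = np.unique(y_dec)
    if stims.size < 2 or decs.size != 2:
        raise ValueError("need ≥2 stimuli and exactly 2 trial types")
    p = X.shape[1]
    sw = np.zeros((p, p))
    n_tot = n_cells = 0
    for s in stims:
        for t in decs:
            g = X[(y_stim == s) & (y_dec == t)]
            if len(g) < 2:
                raise ValueError(f"cell (stim={s}, {t}) has fewer than 2 trials")
            dmean = g - g.mean(axis=0)
            sw += dmean.T @ dmean
            n_tot += len(g)
            n_cells += 1
    sw /= n_tot - n_cells
    sw_reg = (1.0 - shrinkage) * sw + shrinkage * np.diag(np.diag(sw))

    grand = X.mean(axis=0)
    sb = np.zeros_like(sw)
    for s in stims:
        g = X[y_stim == s]
        off = g.mean(axis=0) - grand
        sb += len(g) * np.outer(off, off)
    sb /= len(X)
    eigvals, eigvecs = linalg.eigh(sb, sw_reg)
    span = eigvecs[:, np.argsort(eigvals)[::-1][: stims.size - 1]]
    q, _ = np.linalg.qr(span)

    delta = np.zeros(p)
    vscale = 0.0
    k = stims.size
    for s in stims:
        gm = X[(y_stim == s) & (y_dec == decs[0])]
        gn = X[(y_stim == s) & (y_dec == decs[1])]
        delta += (gm.mean(axis=0) - gn.mean(axis=0)) / k
        vscale += (1.0 / len(gm) + 1.0 / len(gn)) / k**2
    noise_cov = sw * vscale
    in_span = float(np.sum((q.T @ delta) ** 2) - np.trace(q.T @ noise_cov @ q))
    total = float(np.sum(delta**2) - np.trace(noise_cov))
    return in_span, total


def estimate_decision_angle(
    tensors: RateTensor | list[RateTensor],
    trials: list | pd.DataFrame,
    **kwargs,
) -> float:
    """Angle (degrees) between the decision axis and the stimulus span.

    Pools the noise-corrected energy components of
    :func:`decision_angle_components` across sessions before taking the
    ratio.  Values are clipped to [0°, 90°].
    """
    if isinstance(tensors, RateTensor):
        tensors, trials = [tensors], [trials]
    in_span = total = 0.0
    for tensor, tf in zip(tensors, trials):
        a, b = decision_angle_components(tensor, tf, **kwargs)
        in_span += a
        total += b
    if total <= 0:
        raise ValueError("decision signal indistinguishable from noise")
    cos2 = min(max(in_span / total, 0.0), 1.0)
    return float(np.degrees(np.arccos(np.sqrt(cos2))))


def subspace_principal_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Principal angles between span(A) and span(B), degrees, ascending."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError("A and B must be channels × p and channels × q")
    for name, M in (("A", A), ("B", B)):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError(f"{name} does not have full column rank")
    angles = np.rad2deg(linalg.subspace_angles(A, B))
    return np.sort(angles)


def class_separation_score(
    points: np.ndarray, labels: np.ndarray
) -> float:
    """Mean silhouette of the projected points under Euclidean distance.

    Near 1: tight, well-separated classes; near 0: overlapping classes.
    Singleton classes contribute a score of 0 (with a warning), matching the
    convention that their within-class cohesion is undefined.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts == 1):
        warnings.warn(
            "singleton class(es) present; their points are scored 0",
            RuntimeWarning,
            stacklevel=2,
        )
    D = cdist(X, X)
    scores = np.zeros(len(y))
    masks = {c: y == c for c in classes}
    for i in range(len(y)):
        own = masks[y[i]]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: score stays 0
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[c]].mean() for c in classes if c != y[i])
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())
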