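"""Time-resolved population decoding of stimulus identity and choice.

At every time bin an independent shrinkage-LDA classifier is trained on the
trials × channels rate vectors and scored by stratified k-fold
cross-validation (default: one 20-fold partition).  Per-session accuracy
curves are kept separate; averaging, spline interpolation to a fine time
grid, one-sample t-tests against chance, and chance-crossing latency
estimation all operate on the resulting :class:`DecodingCurve`.

The model/results split follows the usual pattern: build a
:class:`PopulationDecoder` from data, call :meth:`~PopulationDecoder.fit`,
inspect the returned :class:`DecodingCurve` (``summary()``, ``latency...``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .lda import crossval_accuracy
from .preprocess import STIMULUS_ALIGNED, RateTensor, bin_firing_rates
from .task import TEST_ONSET_MS, TrialRecord, trials_to_frame

__all__ = [
    "DecodingCurve",
    "PopulationDecoder",
    "time_resolved_decode",
    "interpolate_curve",
    "curve_vs_chance_test",
    "latency_of_chance_crossing",
]


@dataclass(frozen=True)
class DecodingCurve:
    """Per-session and averaged time-resolved decoding accuracy.

    ``per_session_accuracy`` is sessions × times; the dispersion reported by
    :attr:`ci95` is the half-width of the t-based 95% confidence interval of
    the across-session mean.
    """

    times_ms: np.ndarray
    per_session_accuracy: np.ndarray
    chance_level: float
    window_ms: float
    step_ms: float
    interpolated: bool = False
    alignment: str = STIMULUS_ALIGNED

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        a = np.atleast_2d(np.asarray(self.per_session_accuracy, dtype=float))
        if a.shape[1] != t.size:
            raise ValueError("per_session_accuracy must be sessions × times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.interpolated and (np.any(a < 0) or np.any(a > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        if not 0.0 < self.chance_level < 1.0:
            raise ValueError("chance_level must lie in (0, 1)")
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "per_session_accuracy", a)

    @property
    def n_sessions(self) -> int:
        return self.per_session_accuracy.shape[0]

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.per_session_accuracy.mean(axis=0)

    @property
    def ci95(self) -> np.ndarray:
        """Half-width of the 95% CI of the session mean (zero for 1 session)."""
        n = self.n_sessions
        if n < 2:
            return np.zeros(self.times_ms.size)
        sem = self.per_session_accuracy.std(axis=0, ddof=1) / np.sqrt(n)
        return stats.t.ppf(0.975, n - 1) * sem

    def interpolate(self, resolution_ms: float = 2.0) -> "DecodingCurve":
        return interpolate_curve(self, resolution_ms)

    def vs_chance_test(self, t_ms: float) -> tuple[float, float, int]:
        return curve_vs_chance_test(self, t_ms)

    def latency_of_chance_crossing(
        self, test_onset_ms: float = TEST_ONSET_MS, persistence_ms: float = 50.0
    ) -> float | None:
        return latency_of_chance_crossing(self, test_onset_ms, persistence_ms)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (session, time)."""
        s, t = np.meshgrid(
            np.arange(self.n_sessions), self.times_ms, indexing="ij"
        )
        return pd.DataFrame(
            {
                "session": s.ravel(),
                "time_ms": t.ravel(),
                "accuracy": self.per_session_accuracy.ravel(),
            }
        )

    def summary(self) -> str:
        mean = self.mean_accuracy
        peak = int(np.argmax(mean))
        lines = [
            "Time-resolved decoding accuracy",
            "=" * 47,
            f"sessions:        {self.n_sessions}",
            f"time range:      {self.times_ms[0]:.0f}–{self.times_ms[-1]:.0f} ms "
            f"({'interpolated, ' if self.interpolated else ''}step {self.step_ms:g} ms)",
            f"window:          {self.window_ms:g} ms (causal)",
            f"chance level:    {self.chance_level:.4f}",
            f"peak accuracy:   {mean[peak]:.4f} ± {self.ci95[peak]:.4f} "
            f"at {self.times_ms[peak]:.0f} ms",
        ]
        return "\n".join(lines)


def time_resolved_decode(
    tensors: RateTensor | list[RateTensor],
    labels: np.ndarray | list[np.ndarray],
    n_folds: int = 20,
    n_repeats: int = 1,
    seed: int = 0,
    shrinkage: float = 0.1,
    chance_level: float | None = None,
) -> DecodingCurve:
    """Cross-validated accuracy at every time bin, per session.

    All sessions must share a time grid.  ``chance_level`` defaults to one
    over the number of distinct labels.
    """
    if isinstance(tensors, RateTensor):
        tensors, labels = [tensors], [labels]
    if len(tensors) != len(labels):
        raise ValueError("need one label vector per session")
    base = tensors[0]
    for t in tensors[1:]:
        if not np.allclose(t.bin_times_ms, base.bin_times_ms):
            raise ValueError("sessions must share a common time grid")
    if chance_level is None:
        chance_level = 1.0 / np.unique(np.asarray(labels[0])).size

    rng = np.random.default_rng(seed)
    acc = np.zeros((len(tensors), base.n_bins))
    for s, (tensor, y) in enumerate(zip(tensors, labels)):
        y = np.asarray(y)
        if y.shape[0] != tensor.n_trials:
            raise ValueError(f"session {s}: labels do not align with tensor trials")
        for b in range(tensor.n_bins):
            sub_seed = int(rng.integers(2**31))
            try:
                acc[s, b], _ = crossval_accuracy(
                    tensor.values[:, :, b],
                    y,
                    n_folds=n_folds,
                    n_repeats=n_repeats,
                    seed=sub_seed,
                    shrinkage=shrinkage,
                )
            except ValueError as exc:
                raise ValueError(
                    f"decoding failed at bin t={tensor.bin_times_ms[b]:.0f} ms: {exc}"
                ) from exc
    return DecodingCurve(
        times_ms=base.bin_times_ms,
        per_session_accuracy=acc,
        chance_level=float(chance_level),
        window_ms=base.window_ms,
        step_ms=base.step_ms,
        alignment=base.alignment,
    )


class PopulationDecoder:
    """Time-resolved decoder over one or more sessions.

    Parameters mirror the analysis defaults: 150-ms causal windows, 20-fold
    stratified cross-validation, shrinkage 0.1.  Build directly from rate
    tensors and label vectors, or from raw sessions with
    :meth:`from_session`.
    """

    def __init__(
        self,
        tensors: RateTensor | list[RateTensor],
        labels: np.ndarray | list[np.ndarray],
        n_folds: int = 20,
        n_repeats: int = 1,
        shrinkage: float = 0.1,
        chance_level: float | None = None,
    ) -> None:
        self.tensors = tensors
        self.labels = labels
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.shrinkage = shrinkage
        self.chance_level = chance_level

    @classmethod
    def from_session(
        cls,
        events: pd.DataFrame,
        trials: list[TrialRecord] | pd.DataFrame,
        target: str = "stimulus",
        correct_only: bool = True,
        window_ms: float = 150.0,
        step_ms: float | None = None,
        alignment: str = STIMULUS_ALIGNED,
        t_range_ms: tuple[float, float] = (2300.0, 3000.0),
        n_channels: int | None = None,
        **kwargs,
    ) -> "PopulationDecoder":
        """Decode ``target`` ("stimulus" = test-stimulus identity, 3 classes;
        "choice" = match/nonmatch, 2 classes) from one raw session.

        Choice decoding defaults to the finer 10-ms step; only correct trials
        are analyzed unless ``correct_only=False``.
        """
        if target not in ("stimulus", "choice"):
            raise ValueError("target must be 'stimulus' or 'choice'")
        if step_ms is None:
            step_ms = 50.0 if target == "stimulus" else 10.0
        tf = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
        if correct_only:
            tf = tf[tf["correct"]].reset_index(drop=True)
        tensor = bin_firing_rates(
            events, tf, window_ms=window_ms, step_ms=step_ms,
            alignment=alignment, t_range_ms=t_range_ms, n_channels=n_channels,
        )
        y = tf["test_stim" if target == "stimulus" else "trial_type"].to_numpy()
        return cls(tensor, y, **kwargs)

    def fit(self, seed: int = 0) -> DecodingCurve:
        return time_resolved_decode(
            self.tensors,
            self.labels,
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            seed=seed,
            shrinkage=self.shrinkage,
            chance_level=self.chance_level,
        )


def interpolate_curve(curve: DecodingCurve, resolution_ms: float = 2.0) -> DecodingCurve:
    """Natural cubic-spline interpolation of each session's curve.

    Interpolation is applied per session (before any averaging); the spline
    passes through the original knot values exactly.  Requires at least 4
    time points.
    """
    if curve.times_ms.size < 4:
        raise ValueError("need at least 4 time points for cubic-spline interpolation")
    if resolution_ms <= 0:
        raise ValueError("resolution_ms must be > 0")
    t0, t1 = curve.times_ms[0], curve.times_ms[-1]
    fine = np.arange(t0, t1 + resolution_ms * 1e-6, resolution_ms)
    interp = np.vstack(
        [
            CubicSpline(curve.times_ms, row, bc_type="natural")(fine)
            for row in curve.per_session_accuracy
        ]
    )
    return replace(
        curve,
        times_ms=fine,
        per_session_accuracy=interp,
        step_ms=float(resolution_ms),
        interpolated=True,
    )


def curve_vs_chance_test(curve: DecodingCurve, t_ms: float) -> tuple[float, float, int]:
    """One-sample t-test of per-session accuracy at ``t_ms`` against chance.

    Uses the grid point nearest ``t_ms``.  Returns ``(t, two-sided p,
    n_sessions)``; sessions all exactly at chance give ``(0.0, 1.0, n)``.
    """
    n = curve.n_sessions
    if n < 2:
        raise ValueError("t-test against chance needs at least 2 sessions")
    idx = int(np.argmin(np.abs(curve.times_ms - t_ms)))
    vals = curve.per_session_accuracy[:, idx]
    if np.allclose(vals, curve.chance_level):
        return 0.0, 1.0, n
    res = stats.ttest_1samp(vals, curve.chance_level)
    return float(res.statistic), float(res.pvalue), n


def latency_of_chance_crossing(
    curve: DecodingCurve,
    test_onset_ms: float = TEST_ONSET_MS,
    persistence_ms: float = 50.0,
) -> float | None:
    """First persistent chance crossing of the session-mean curve.

    Scans times strictly after ``test_onset_ms`` for the first point at which
    the mean accuracy exceeds chance and remains above it for
    ``persistence_ms`` (or through the end of the curve).  Returns the
    crossing time relative to test onset, or None if no crossing qualifies.
    Meant to be applied to an interpolated curve.
    """
    mean = curve.mean_accuracy
    times = curve.times_ms
    above = mean > curve.chance_level
    dt = times[1] - times[0] if times.size > 1 else persistence_ms
    n_persist = max(int(np.floor(persistence_ms / dt + 1e-9)) + 1, 1)
    candidates = np.flatnonzero(above & (times > test_onset_ms))
    for i in candidates:
        run = above[i : i + n_persist]
        if run.all():
            return float(times[i] - test_onset_ms)
    return None
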