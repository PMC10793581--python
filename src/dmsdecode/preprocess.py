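"""From raw traces and spike events to aligned firing-rate tensors.

Two stages live here:

* ``detect_spikes`` — threshold crossing on a bandpassed voltage trace
  (multi-unit activity): events where the absolute signal first exceeds a
  multiple of the trace's standard deviation, with a dead time so each
  excursion yields one event.

* ``bin_firing_rates`` — spike counts in *causal* moving windows.  A window
  labeled by time ``t`` covers the half-open interval ``(t − w, t]``, so the
  rate at ``t`` never depends on spikes after ``t``.  Rates are counts divided
  by the window length, in spikes/s.  Trials can be aligned to stimulus onset
  (the common trial clock) or to the behavioral response (0 = test onset + RT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import TEST_ONSET_MS, TrialRecord, trials_to_frame

__all__ = ["RateTensor", "detect_spikes", "bin_firing_rates", "align_to_response"]

STIMULUS_ALIGNED = "stimulus_onset"
RESPONSE_ALIGNED = "response_onset"


@dataclass(frozen=True)
class RateTensor:
    """Trials × channels × time-bins firing rates with an explicit time base.

    ``bin_times_ms`` holds the right edge of each causal window.  Under
    stimulus alignment times are on the trial clock (0 = fixation onset);
    under response alignment 0 is the moment of the lever response.
    """

    values: np.ndarray  # (n_trials, n_channels, n_bins), spikes/s
    bin_times_ms: np.ndarray
    window_ms: float
    step_ms: float
    alignment: str
    trial_index: np.ndarray  # trial_id per row of values

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.bin_times_ms, dtype=float)
        idx = np.asarray(self.trial_index)
        if v.ndim != 3:
            raise ValueError("values must be trials × channels × bins")
        if t.shape != (v.shape[2],):
            raise ValueError("bin_times_ms length must match the bin axis")
        if idx.shape != (v.shape[0],):
            raise ValueError("trial_index length must match the trial axis")
        if t.size > 1:
            steps = np.diff(t)
            if not np.all(steps > 0) or not np.allclose(steps, steps[0], atol=1e-9):
                raise ValueError("bin times must increase with a constant step")
        if np.any(v < 0):
            raise ValueError("rates must be non-negative")
        if self.alignment not in (STIMULUS_ALIGNED, RESPONSE_ALIGNED):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "bin_times_ms", t)
        object.__setattr__(self, "trial_index", idx)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def bin_at(self, t_ms: float) -> int:
        """Index of the bin whose label time is nearest ``t_ms``."""
        return int(np.argmin(np.abs(self.bin_times_ms - t_ms)))

    def at_time(self, t_ms: float) -> np.ndarray:
        """Trials × channels rate matrix at the bin nearest ``t_ms``."""
        return self.values[:, :, self.bin_at(t_ms)]

    def select_trials(self, mask: np.ndarray) -> "RateTensor":
        mask = np.asarray(mask)
        return replace(self, values=self.values[mask], trial_index=self.trial_index[mask])


def detect_spikes(
    filtered_signal: np.ndarray,
    threshold_multiplier: float = 4.0,
    dead_time_ms: float = 1.0,
    sampling_rate_hz: float = 25_000.0,
    robust: bool = False,
) -> np.ndarray:
    """Threshold-crossing event times (ms) from a bandpassed trace.

    The threshold is ``threshold_multiplier`` times the standard deviation of
    the whole trace (or 1.4826×MAD when ``robust``); an event is recorded at
    each sample where ``|signal|`` first reaches the threshold, and further
    crossings within ``dead_time_ms`` are suppressed.
    """
    x = np.asarray(filtered_signal, dtype=float).ravel()
    if dead_time_ms <= 0:
        raise ValueError("dead_time_ms must be > 0")
    if robust:
        sd = 1.4826 * np.median(np.abs(x - np.median(x)))
    else:
        sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("zero-variance signal: threshold undefined")
    thresh = threshold_multiplier * sd

    above = np.abs(x) >= thresh
    if not above.any():
        return np.empty(0, dtype=float)
    idx = np.flatnonzero(above)
    dead_samples = dead_time_ms * sampling_rate_hz / 1000.0
    events = [idx[0]]
    for i in idx[1:]:
        if i - events[-1] > dead_samples:
            events.append(i)
    return np.asarray(events, dtype=float) * 1000.0 / sampling_rate_hz


def _as_frames(
    events: pd.DataFrame, trials: list[TrialRecord] | pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    tf = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    return events, tf


def bin_firing_rates(
    events: pd.DataFrame,
    trials: list[TrialRecord] | pd.DataFrame,
    window_ms: float = 150.0,
    step_ms: float = 50.0,
    alignment: str = STIMULUS_ALIGNED,
    t_range_ms: tuple[float, float] = (0.0, 3000.0),
    n_channels: int | None = None,
    test_onset_ms: float = TEST_ONSET_MS,
) -> RateTensor:
    """Count spikes in causal moving windows and convert to rates.

    Window labels run from ``t_range_ms[0] + window_ms`` to ``t_range_ms[1]``
    in steps of ``step_ms``; each window covers ``(t − window_ms, t]`` so no
    window extends before the start of the range.  Under response alignment
    each trial's spike times are first shifted so 0 marks the lever response
    (``test_onset + rt``), and ``t_range_ms`` is interpreted on that
    response-relative axis (negative = before the response).
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window_ms and step_ms must be > 0")
    events, tf = _as_frames(events, trials)
    trial_ids = tf["trial_id"].to_numpy()
    if n_channels is None:
        n_channels = int(events["channel"].max()) + 1 if len(events) else 1

    t0, t1 = float(t_range_ms[0]), float(t_range_ms[1])
    first = t0 + window_ms
    if first > t1 + 1e-9:
        raise ValueError("t_range too short for one full causal window")
    n_bins = int(np.floor((t1 - first) / step_ms + 1e-9)) + 1
    bin_times = first + step_ms * np.arange(n_bins)

    # Events from trials absent from the trial table (e.g. excluded error
    # trials) are dropped.
    events = events[events["trial_id"].isin(trial_ids)]

    times = events["spike_time_ms"].to_numpy(dtype=float)
    if alignment == RESPONSE_ALIGNED:
        rts = tf.set_index("trial_id")["rt_ms"]
        if rts.isna().any():
            bad = rts.index[rts.isna()][0]
            raise ValueError(f"response alignment requires rt_ms on every trial (trial {bad})")
        shift = (test_onset_ms + rts).reindex(events["trial_id"]).to_numpy(dtype=float)
        times = times - shift
    elif alignment != STIMULUS_ALIGNED:
        raise ValueError(f"unknown alignment {alignment!r}")

    row = pd.Series(np.arange(len(trial_ids)), index=trial_ids)
    trial_rows = row.reindex(events["trial_id"]).to_numpy()

    values = np.zeros((len(trial_ids), n_channels, n_bins))
    in_span = (times > t0) & (times <= bin_times[-1])
    tr = trial_rows[in_span].astype(np.int64)
    ch = events["channel"].to_numpy()[in_span]
    tt = times[in_span]
    # A spike at time s falls in every window (t−w, t] with s ≤ t < s + w:
    # bins k with first + k·step ≥ s and first + k·step < s + w.
    k_lo = np.ceil((tt - first) / step_ms - 1e-9).astype(np.int64)
    k_hi = np.ceil((tt + window_ms - first) / step_ms - 1e-9).astype(np.int64)
    np.clip(k_lo, 0, n_bins, out=k_lo)
    np.clip(k_hi, 0, n_bins, out=k_hi)
    for dk in range(int((k_hi - k_lo).max(initial=0))):
        hit = k_lo + dk < k_hi
        np.add.at(values, (tr[hit], ch[hit], k_lo[hit] + dk), 1.0)
    values *= 1000.0 / window_ms

    return RateTensor(
        values=values,
        bin_times_ms=bin_times,
        window_ms=float(window_ms),
        step_ms=float(step_ms),
        alignment=alignment,
        trial_index=trial_ids,
    )


def align_to_response(
    events: pd.DataFrame,
    trials: list[TrialRecord] | pd.DataFrame,
    test_onset_ms: float = TEST_ONSET_MS,
) -> pd.DataFrame:
    """Shift spike times so 0 marks the behavioral response of each trial.

    Returns a copy of the event table with ``spike_time_ms`` replaced by time
    relative to ``test_onset + rt`` (negative before the response).
    """
    events, tf = _as_frames(events, trials)
    rts = tf.set_index("trial_id")["rt_ms"]
    if rts.isna().any():
        bad = rts.index[rts.isna()][0]
        raise ValueError(f"response alignment requires rt_ms on every trial (trial {bad})")
    events = events[events["trial_id"].isin(set(tf["trial_id"]))].reset_index(drop=True)
    shift = (test_onset_ms + rts).reindex(events["trial_id"]).to_numpy(dtype=float)
    out = events.copy()
    out["spike_time_ms"] = events["spike_time_ms"].to_numpy(dtype=float) - shift
    return out
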