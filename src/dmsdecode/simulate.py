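"""Synthetic DMS sessions with known ground-truth coding structure.

The generator emulates a multi-channel (multi-unit) V1 recording during the
delayed match-to-sample task: each channel fires as an inhomogeneous Poisson
process whose rate is the sum of

* a constant baseline,
* stimulus tuning, active (after a short visual latency) while the sample or
  test stimulus is on screen and keyed to the displayed stimulus, and
* an additive choice signal along a fixed population direction, switched on
  a configurable latency after test onset with a linear ramp, signed by the
  forthcoming lever movement (forward = +, backward = −), and switched off at
  the response.

Because the choice signal follows the *choice*, on error trials it is inverted
relative to the match/nonmatch trial type — the property the cross-condition
(correct→error) analysis is designed to detect.  Every tuning direction,
latency and amplitude is a config field, so downstream stages can be tested
by parameter recovery.

Spike times are drawn by thinning: homogeneous candidates at each channel's
rate ceiling, accepted with probability rate(t)/ceiling.  Rates are clipped at
zero; configs whose clipped time mass exceeds a small tolerance are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .task import (
    BACKWARD,
    EVENT_COLUMNS,
    FORWARD,
    MATCH,
    NONMATCH,
    TrialRecord,
    assign_choice,
)

__all__ = [
    "SimulationConfig",
    "default_config",
    "default_stim_gain",
    "decision_direction_at_angle",
    "stimulus_contrast_span",
    "generate_session",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one synthetic recording session.

    Rates are in spikes/s, durations and latencies in ms.  ``stim_gain`` is an
    ``n_channels × n_stimuli`` additive rate modulation applied while the
    corresponding stimulus is displayed; ``decision_direction`` is a unit
    vector over channels along which the choice signal of amplitude
    ``decision_gain`` is added.  ``decision_angle_deg`` records the intended
    principal angle between that direction and the span of stimulus-tuning
    contrasts (informational once ``decision_direction`` is set explicitly).
    """

    n_trials: int
    n_channels: int = 32
    n_stimuli: int = 3
    p_match: float = 0.5
    error_rate: float = 0.2
    fixation_ms: float = 500.0
    sample_ms: float = 500.0
    delay_ms: float = 1500.0
    test_max_ms: float = 500.0
    baseline_rate: float = 10.0
    stim_gain: np.ndarray | None = None
    visual_latency_ms: float = 50.0
    decision_direction: np.ndarray | None = None
    decision_gain: float = 5.0
    decision_latency_ms: float = 150.0
    decision_ramp_ms: float = 100.0
    decision_angle_deg: float = 90.0
    signal_follows: str = "choice"  # or "trial_type"
    rt_mean_ms: float = 600.0
    rt_sd_ms: float = 150.0
    post_response_ms: float = 200.0
    max_clipped_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_channels < 1 or self.n_stimuli < 2:
            raise ValueError("need n_trials ≥ 1, n_channels ≥ 1, n_stimuli ≥ 2")
        for name in ("p_match", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("fixation_ms", "sample_ms", "delay_ms", "test_max_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"epoch duration {name} must be > 0")
        if self.baseline_rate < 0 or self.decision_gain < 0:
            raise ValueError("rates must be non-negative")
        if self.signal_follows not in ("choice", "trial_type"):
            raise ValueError("signal_follows must be 'choice' or 'trial_type'")
        if self.rt_mean_ms <= 0 or self.rt_sd_ms <= 0:
            raise ValueError("rt_mean_ms and rt_sd_ms must be > 0")
        if self.stim_gain is not None:
            g = np.asarray(self.stim_gain, dtype=float)
            if g.shape != (self.n_channels, self.n_stimuli):
                raise ValueError(
                    f"stim_gain shape {g.shape} != (n_channels, n_stimuli) "
                    f"= ({self.n_channels}, {self.n_stimuli})"
                )
            object.__setattr__(self, "stim_gain", g)
        if self.decision_direction is not None:
            d = np.asarray(self.decision_direction, dtype=float).ravel()
            if d.shape != (self.n_channels,):
                raise ValueError("decision_direction length must equal n_channels")
            nrm = float(np.linalg.norm(d))
            if not np.isclose(nrm, 1.0, atol=1e-6):
                raise ValueError(f"decision_direction must have unit norm (got {nrm:.6f})")
            object.__setattr__(self, "decision_direction", d)

    # Epoch onsets on the trial clock (0 = fixation onset).
    @property
    def sample_onset_ms(self) -> float:
        return self.fixation_ms

    @property
    def test_onset_ms(self) -> float:
        return self.fixation_ms + self.sample_ms + self.delay_ms

    def resolve(self) -> "SimulationConfig":
        """Fill in stim_gain / decision_direction from the seed if unset."""
        cfg = self
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x5EED]))
        if cfg.stim_gain is None:
            cfg = replace(cfg, stim_gain=default_stim_gain(cfg.n_channels, cfg.n_stimuli, rng))
        if cfg.decision_direction is None:
            try:
                direction = decision_direction_at_angle(
                    cfg.stim_gain, cfg.decision_angle_deg, rng
                )
            except ValueError:
                # Degenerate tuning (e.g. no stimulus drive): the angle
                # constraint is vacuous, any unit direction will do.
                v = rng.standard_normal(cfg.n_channels)
                direction = v / np.linalg.norm(v)
            cfg = replace(cfg, decision_direction=direction)
        return cfg


def default_stim_gain(
    n_channels: int, n_stimuli: int, rng: np.random.Generator
) -> np.ndarray:
    """Tuning matrix with one preferred stimulus per channel.

    Each channel responds to a single preferred stimulus with an amplitude
    drawn uniformly from 6–10 spikes/s; preferences cycle through the stimuli
    so every stimulus drives roughly n_channels/n_stimuli channels.
    """
    gain = np.zeros((n_channels, n_stimuli))
    preferred = np.arange(n_channels) % n_stimuli
    amps = rng.uniform(6.0, 10.0, size=n_channels)
    gain[np.arange(n_channels), preferred] = amps
    return gain


def stimulus_contrast_span(stim_gain: np.ndarray) -> np.ndarray:
    """Orthonormal basis (channels × (n_stimuli−1)) of the tuning-contrast span.

    The span of the mean-centered tuning vectors: the directions along which
    the population rate differs between stimuli.
    """
    g = np.asarray(stim_gain, dtype=float)
    centered = g - g.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if rank < g.shape[1] - 1:
        raise ValueError("stimulus tuning contrasts are rank deficient")
    return u[:, : g.shape[1] - 1]


def decision_direction_at_angle(
    stim_gain: np.ndarray, angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit population vector at a given principal angle to the contrast span.

    ``angle_deg = 90`` puts the choice signal orthogonal to every stimulus
    contrast; ``0`` embeds it inside the stimulus-coding subspace.
    """
    if not 0.0 <= angle_deg <= 90.0:
        raise ValueError("angle_deg must be in [0, 90]")
    q = stimulus_contrast_span(stim_gain)
    n_channels = q.shape[0]
    # Unit vector inside the span.
    w = rng.standard_normal(q.shape[1])
    u_in = q @ (w / np.linalg.norm(w))
    # Unit vector orthogonal to the span.
    v = rng.standard_normal(n_channels)
    v -= q @ (q.T @ v)
    v /= np.linalg.norm(v)
    theta = np.deg2rad(angle_deg)
    d = np.cos(theta) * u_in + np.sin(theta) * v
    return d / np.linalg.norm(d)


def default_config(n_trials: int = 600, seed: int = 0, **overrides) -> SimulationConfig:
    """Standard session configuration with seed-derived tuning structure."""
    return SimulationConfig(n_trials=n_trials, seed=seed, **overrides).resolve()


# ---------------------------------------------------------------------------
# rate model


def _ramp(t: np.ndarray, onset: float, ramp_ms: float, offset: float) -> np.ndarray:
    """Linear 0→1 ramp starting at ``onset``, zeroed at/after ``offset``."""
    if ramp_ms <= 0:
        f = (t >= onset).astype(float)
    else:
        f = np.clip((t - onset) / ramp_ms, 0.0, 1.0)
    return np.where(t < offset, f, 0.0)


def _trial_rate(
    cfg: SimulationConfig,
    channels: np.ndarray,
    times: np.ndarray,
    sample_stim: int,
    test_stim: int,
    sign: float,
    rt_ms: float,
) -> np.ndarray:
    """Instantaneous rate (spikes/s) for (channel, time) pairs of one trial."""
    vl = cfg.visual_latency_ms
    t0 = cfg.test_onset_ms
    r = np.full(times.shape, cfg.baseline_rate, dtype=float)

    s_on, s_off = cfg.sample_onset_ms + vl, cfg.sample_onset_ms + cfg.sample_ms + vl
    in_sample = (times >= s_on) & (times < s_off)
    r[in_sample] += cfg.stim_gain[channels[in_sample], sample_stim]

    test_off = t0 + min(rt_ms, cfg.test_max_ms)
    in_test = (times >= t0 + vl) & (times < test_off + vl)
    r[in_test] += cfg.stim_gain[channels[in_test], test_stim]

    f = _ramp(times, t0 + cfg.decision_latency_ms, cfg.decision_ramp_ms, t0 + rt_ms)
    r += sign * cfg.decision_gain * cfg.decision_direction[channels] * f
    return np.clip(r, 0.0, None)


def _clipped_fraction(cfg: SimulationConfig) -> float:
    """Worst-case fraction of channel-time driven below zero before clipping.

    Evaluated on a 1-ms grid with the choice signal at full amplitude against
    each channel (stimulus tuning is additive and non-negative, so omitting it
    is conservative).
    """
    t_end = cfg.test_onset_ms + max(cfg.test_max_ms, cfg.rt_mean_ms + cfg.post_response_ms)
    t = np.arange(0.0, t_end, 1.0)
    f = _ramp(t, cfg.test_onset_ms + cfg.decision_latency_ms, cfg.decision_ramp_ms,
              cfg.test_onset_ms + cfg.rt_mean_ms)
    drive = cfg.decision_gain * np.abs(cfg.decision_direction)[:, None] * f[None, :]
    return float((cfg.baseline_rate - drive < 0).mean())


def _draw_rt(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Reaction times: normal truncated at zero."""
    a = (0.0 - cfg.rt_mean_ms) / cfg.rt_sd_ms
    return stats.truncnorm.rvs(
        a, np.inf, loc=cfg.rt_mean_ms, scale=cfg.rt_sd_ms, size=size, random_state=rng
    )


def _balanced_cells(n_items: int, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Assign items to cells as evenly as possible, remainder randomized."""
    base, extra = divmod(n_items, n_cells)
    counts = np.full(n_cells, base)
    counts[rng.choice(n_cells, size=extra, replace=False)] += 1
    return counts


def _draw_labels(cfg: SimulationConfig, rng: np.random.Generator) -> list[TrialRecord]:
    """Pseudo-randomized trial sequence with counterbalanced conditions.

    Match/nonmatch counts follow ``p_match`` deterministically (as in the
    task, where they were randomized to be equal), and stimulus pairs are
    counterbalanced within each trial type, so trial type and test-stimulus
    identity are unconfounded by design.  Errors and reaction times are drawn
    independently per trial.
    """
    n = cfg.n_trials
    k = cfg.n_stimuli
    n_match = int(round(n * cfg.p_match))
    match_counts = _balanced_cells(n_match, k, rng)
    pairs = [(s, s) for s in range(k)]
    counts = list(match_counts)
    nonmatch_pairs = [(s, t) for s in range(k) for t in range(k) if t != s]
    counts += list(_balanced_cells(n - n_match, len(nonmatch_pairs), rng))
    pairs += nonmatch_pairs
    sample = np.concatenate([np.full(c, s) for (s, _), c in zip(pairs, counts)])
    test = np.concatenate([np.full(c, t) for (_, t), c in zip(pairs, counts)])
    # Errors occur uniformly across stimulus-pair cells (no cell is harder
    # than another), so the correct-trial subset stays counterbalanced and
    # trial type remains unconfounded with stimulus identity.
    correct = np.ones(n, dtype=bool)
    start = 0
    for c in counts:
        n_err = int(np.floor(c * cfg.error_rate))
        if rng.random() < c * cfg.error_rate - n_err:
            n_err += 1
        if n_err:
            correct[start + rng.choice(c, size=n_err, replace=False)] = False
        start += c
    order = rng.permutation(n)
    sample, test, correct = sample[order], test[order], correct[order]
    is_match = sample == test
    rt = _draw_rt(cfg, rng, n)
    records = []
    for i in range(n):
        ttype = MATCH if is_match[i] else NONMATCH
        records.append(
            TrialRecord(
                trial_id=i,
                sample_stim=int(sample[i]),
                test_stim=int(test[i]),
                trial_type=ttype,
                choice=assign_choice(ttype, bool(correct[i])),
                correct=bool(correct[i]),
                rt_ms=float(rt[i]),
            )
        )
    return records


def generate_session(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[TrialRecord]]:
    """Simulate one session: spike events plus per-trial labels.

    Returns a long-form spike table with columns ``(trial_id, channel,
    spike_time_ms)`` sorted by trial, channel and time, and the list of
    :class:`~dmsdecode.task.TrialRecord`.  Identical configs (including the
    seed) produce identical output.
    """
    cfg = config.resolve()
    frac = _clipped_fraction(cfg)
    if frac > cfg.max_clipped_fraction:
        raise ValueError(
            f"config drives rates negative over {frac:.1%} of channel-time "
            f"(limit {cfg.max_clipped_fraction:.1%}); reduce decision_gain or "
            f"raise baseline_rate"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xD5]))
    trials = _draw_labels(cfg, rng)

    # Per-channel rate ceiling for thinning.
    ceiling = (
        cfg.baseline_rate
        + cfg.stim_gain.max(axis=1)
        + cfg.decision_gain * np.abs(cfg.decision_direction)
    )
    ceiling = np.maximum(ceiling, 1e-12)

    all_trial_ids: list[np.ndarray] = []
    all_channels: list[np.ndarray] = []
    all_times: list[np.ndarray] = []
    for rec in trials:
        t_end = cfg.test_onset_ms + max(cfg.test_max_ms, rec.rt_ms + cfg.post_response_ms)
        n_cand = rng.poisson(ceiling * t_end / 1000.0)
        channels = np.repeat(np.arange(cfg.n_channels), n_cand)
        times = rng.uniform(0.0, t_end, size=channels.size)
        if cfg.signal_follows == "choice":
            sign = 1.0 if rec.choice == FORWARD else -1.0
        else:
            sign = 1.0 if rec.trial_type == MATCH else -1.0
        rate = _trial_rate(cfg, channels, times, rec.sample_stim, rec.test_stim, sign, rec.rt_ms)
        keep = rng.uniform(0.0, 1.0, size=channels.size) * ceiling[channels] < rate
        all_trial_ids.append(np.full(int(keep.sum()), rec.trial_id, dtype=np.int64))
        all_channels.append(channels[keep])
        all_times.append(times[keep])

    events = pd.DataFrame(
        {
            "trial_id": np.concatenate(all_trial_ids),
            "channel": np.concatenate(all_channels).astype(np.int64),
            "spike_time_ms": np.concatenate(all_times),
        }
    )
    events = events.sort_values(list(EVENT_COLUMNS), kind="mergesort", ignore_index=True)
    return events, trials
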