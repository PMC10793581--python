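"""Trial structure of the delayed match-to-sample (DMS) task.

A trial runs on a single millisecond clock starting at fixation onset:

    0 ........ fixation (blank screen)
    500 ...... sample stimulus onset (500 ms)
    1000 ..... delay onset (1500 ms)
    2500 ..... test stimulus onset (up to 500 ms, or until the response)

The subject reports whether the test stimulus matches the sample by moving a
two-way lever: forward on match trials, backward on nonmatch trials.  The
reaction time (``rt_ms``) is measured from test onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Epoch onsets on the trial clock (ms from fixation onset).
FIXATION_ONSET_MS = 0.0
SAMPLE_ONSET_MS = 500.0
DELAY_ONSET_MS = 1000.0
TEST_ONSET_MS = 2500.0

MATCH = "match"
NONMATCH = "nonmatch"
FORWARD = "forward"
BACKWARD = "backward"

#: Column order of a spike-event table (one row per spike).
EVENT_COLUMNS = ("trial_id", "channel", "spike_time_ms")

#: Column order of a trial-record table (one row per trial).
TRIAL_COLUMNS = (
    "trial_id",
    "sample_stim",
    "test_stim",
    "trial_type",
    "choice",
    "correct",
    "rt_ms",
)


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial labels: stimuli, match/nonmatch type, choice, outcome, RT."""

    trial_id: int
    sample_stim: int
    test_stim: int
    trial_type: str  # MATCH or NONMATCH
    choice: str  # FORWARD or BACKWARD
    correct: bool
    rt_ms: float

    def __post_init__(self) -> None:
        if self.trial_type not in (MATCH, NONMATCH):
            raise ValueError(f"invalid trial_type {self.trial_type!r}")
        if self.choice not in (FORWARD, BACKWARD):
            raise ValueError(f"invalid choice {self.choice!r}")
        if (self.trial_type == MATCH) != (self.sample_stim == self.test_stim):
            raise ValueError(
                f"trial {self.trial_id}: trial_type {self.trial_type!r} inconsistent "
                f"with stimuli ({self.sample_stim}, {self.test_stim})"
            )
        expected = assign_choice(self.trial_type, self.correct)
        if self.choice != expected:
            raise ValueError(
                f"trial {self.trial_id}: choice {self.choice!r} inconsistent with "
                f"trial_type={self.trial_type!r}, correct={self.correct}"
            )
        if not self.rt_ms > 0:
            raise ValueError(f"trial {self.trial_id}: rt_ms must be > 0")


def assign_choice(trial_type: str, correct: bool) -> str:
    """Lever direction implied by trial type and outcome.

    The correct report is forward on match trials and backward on nonmatch
    trials; an incorrect trial carries the opposite lever movement.
    """
    if trial_type not in (MATCH, NONMATCH):
        raise ValueError(f"invalid trial_type {trial_type!r}")
    if trial_type == MATCH:
        return FORWARD if correct else BACKWARD
    return BACKWARD if correct else FORWARD


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records with the documented column order."""
    return pd.DataFrame(
        [
            (t.trial_id, t.sample_stim, t.test_stim, t.trial_type, t.choice, t.correct, t.rt_ms)
            for t in trials
        ],
        columns=list(TRIAL_COLUMNS),
    )


def trials_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild (and re-validate) trial records from a table."""
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return [
        TrialRecord(
            trial_id=int(row.trial_id),
            sample_stim=int(row.sample_stim),
            test_stim=int(row.test_stim),
            trial_type=str(row.trial_type),
            choice=str(row.choice),
            correct=bool(row.correct),
            rt_ms=float(row.rt_ms),
        )
        for row in frame.itertuples(index=False)
    ]


def trial_end_ms(rt_ms: float, test_max_ms: float = 500.0, post_response_ms: float = 200.0) -> float:
    """End of the recorded span of one trial, on the trial clock.

    Recording covers the full potential test epoch and a short tail after the
    response, whichever ends later.
    """
    return TEST_ONSET_MS + max(float(test_max_ms), float(rt_ms) + float(post_response_ms))


def response_time_on_trial_clock(trials: pd.DataFrame | list[TrialRecord]) -> np.ndarray:
    """Absolute response times (test onset + RT) per trial, in ms."""
    if isinstance(trials, pd.DataFrame):
        rt = trials["rt_ms"].to_numpy(dtype=float)
    else:
        rt = np.array([t.rt_ms for t in trials], dtype=float)
    return TEST_ONSET_MS + rt
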