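"""Correct→error generalization test for choice coding.

Decoders are trained on *correct* trials to predict match/nonmatch and then
applied to *error* trials, in which the animal's choice is inverted relative
to the trial type.  A decoder tracking the physical trial type generalizes
(error-trial accuracy above chance); a decoder tracking the forthcoming
choice misclassifies errors systematically (accuracy below chance,
mirroring the held-out correct-trial accuracy about 0.5).

The rate vector is taken at a single reference time (default 2900 ms: the
causal 150-ms window ending 400 ms after test onset), and trials whose
response precedes that window (rt < 400 ms by default) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .lda import fit_lda
from .preprocess import RateTensor
from .task import TrialRecord, trials_to_frame

__all__ = ["CrossConditionResult", "CrossConditionDecoder", "cross_condition_test"]


@dataclass(frozen=True)
class CrossConditionResult:
    """Held-out correct-trial accuracy and error-trial transfer accuracy."""

    accuracy_correct: float
    accuracy_error: float
    per_fold_correct: np.ndarray
    per_fold_error: np.ndarray
    t_ms: float
    rt_exclude_ms: float
    n_correct: int
    n_error: int

    def summary(self) -> str:
        lines = [
            "Correct→error cross-condition decoding (match/nonmatch)",
            "=" * 55,
            f"reference time:          {self.t_ms:.0f} ms "
            f"(trials with rt < {self.rt_exclude_ms:.0f} ms excluded)",
            f"correct trials:          {self.n_correct}",
            f"error trials:            {self.n_error}",
            f"held-out correct acc.:   {self.accuracy_correct:.4f}",
            f"error-trial transfer:    {self.accuracy_error:.4f}",
            f"chance level:            0.5000",
        ]
        verdict = (
            "below-chance transfer: decoder tracks the forthcoming CHOICE"
            if self.accuracy_error < 0.5
            else "above-chance transfer: decoder generalizes over trial TYPE"
        )
        lines.append(f"interpretation:          {verdict}")
        return "\n".join(lines)


def cross_condition_test(
    tensor: RateTensor,
    trials: list[TrialRecord] | pd.DataFrame,
    t_ms: float = 2900.0,
    rt_exclude_ms: float = 400.0,
    n_folds: int = 20,
    seed: int = 0,
    shrinkage: float = 0.1,
) -> CrossConditionResult:
    """Train on correct trials, transfer to error trials, at one time point.

    The tensor must cover all trials in ``trials`` (its ``trial_index`` is
    matched against the trial table).  Within each cross-validation step the
    decoder fitted on the correct-trial training fold is scored on (i) the
    held-out correct fold and (ii) *all* retained error trials; both
    accuracies are averaged over folds.
    """
    tf = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    tf = tf.set_index("trial_id").loc[tensor.trial_index].reset_index()

    X = tensor.at_time(t_ms)
    keep = tf["rt_ms"].to_numpy(dtype=float) >= rt_exclude_ms
    correct = tf["correct"].to_numpy(dtype=bool)
    y = tf["trial_type"].to_numpy()

    cor_mask = keep & correct
    err_mask = keep & ~correct
    if err_mask.sum() == 0:
        raise ValueError(
            f"no error trials remain after excluding rt < {rt_exclude_ms} ms"
        )
    Xc, yc = X[cor_mask], y[cor_mask]
    Xe, ye = X[err_mask], y[err_mask]

    counts = np.unique(yc, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("each trial type needs at least 2 correct trials")
    if counts.max() > 3 * counts.min():
        warnings.warn(
            "strong match/nonmatch imbalance among correct trials; "
            "stratification may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    folds = min(n_folds, int(counts.min()))
    if folds < n_folds:
        warnings.warn(
            f"reducing folds from {n_folds} to {folds}: smallest class has "
            f"{counts.min()} correct trials",
            RuntimeWarning,
            stacklevel=2,
        )

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % 2**31)
    acc_c, acc_e = [], []
    for train, test in splitter.split(Xc, yc):
        model = fit_lda(Xc[train], yc[train], shrinkage=shrinkage)
        acc_c.append(float(np.mean(model.predict(Xc[test]) == yc[test])))
        acc_e.append(float(np.mean(model.predict(Xe) == ye)))
    per_c, per_e = np.asarray(acc_c), np.asarray(acc_e)
    return CrossConditionResult(
        accuracy_correct=float(per_c.mean()),
        accuracy_error=float(per_e.mean()),
        per_fold_correct=per_c,
        per_fold_error=per_e,
        t_ms=float(t_ms),
        rt_exclude_ms=float(rt_exclude_ms),
        n_correct=int(cor_mask.sum()),
        n_error=int(err_mask.sum()),
    )


class CrossConditionDecoder:
    """Model-style wrapper: configure once, ``fit(seed)`` to run the test."""

    def __init__(
        self,
        tensor: RateTensor,
        trials: list[TrialRecord] | pd.DataFrame,
        t_ms: float = 2900.0,
        rt_exclude_ms: float = 400.0,
        n_folds: int = 20,
        shrinkage: float = 0.1,
    ) -> None:
        self.tensor = tensor
        self.trials = trials
        self.t_ms = t_ms
        self.rt_exclude_ms = rt_exclude_ms
        self.n_folds = n_folds
        self.shrinkage = shrinkage

    def fit(self, seed: int = 0) -> CrossConditionResult:
        return cross_condition_test(
            self.tensor,
            self.trials,
            t_ms=self.t_ms,
            rt_exclude_ms=self.rt_exclude_ms,
            n_folds=self.n_folds,
            seed=seed,
            shrinkage=self.shrinkage,
        )
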