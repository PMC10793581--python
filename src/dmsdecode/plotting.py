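"""Minimal plots: decoding curves and 3-D state-space trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decoding import DecodingCurve

__all__ = ["plot_decoding_curve", "plot_trajectories_3d"]


def plot_decoding_curve(curve: DecodingCurve, ax=None, test_onset_ms: float | None = 2500.0):
    """Session-mean accuracy with 95% CI band and the chance line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    mean, ci = curve.mean_accuracy, curve.ci95
    ax.fill_between(curve.times_ms, mean - ci, mean + ci, alpha=0.3, lw=0)
    ax.plot(curve.times_ms, mean, lw=1.5)
    ax.axhline(curve.chance_level, ls=":", color="k", lw=1)
    if test_onset_ms is not None:
        ax.axvline(test_onset_ms, ls="--", color="gray", lw=1)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("decoding accuracy")
    ax.set_ylim(0, 1)
    return ax


def plot_trajectories_3d(
    trajectories: np.ndarray,
    trials: pd.DataFrame,
    trial_index: np.ndarray,
    ax=None,
):
    """Condition-averaged trajectories in [stim 1, stim 2, decision] space.

    Solid lines: forward (match) choices; dashed: backward. Color by test
    stimulus.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="3d")
    tf = trials.set_index("trial_id").loc[trial_index].reset_index()
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for (stim, choice), grp in tf.groupby(["test_stim", "choice"], sort=True):
        mean = trajectories[grp.index.to_numpy()].mean(axis=0)
        ax.plot(
            mean[:, 0], mean[:, 1], mean[:, 2],
            color=colors[int(stim) % len(colors)],
            ls="-" if choice == "forward" else "--",
            label=f"stim {stim}, {choice}",
        )
    ax.set_xlabel("stimulus axis 1")
    ax.set_ylabel("stimulus axis 2")
    ax.set_zlabel("decision axis")
    ax.legend(fontsize=7)
    return ax
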