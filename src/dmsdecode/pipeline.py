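"""End-to-end orchestration: simulate → bin → decode → crosstest → subspace.

``run_pipeline`` executes the full analysis on one or more (synthetic)
sessions and writes per-session decoding curves (CSV) and a summary JSON
stamped with the config hash, seed and package version.  Every stage failure
aborts with the stage name and a reproduction hint.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cross_condition import cross_condition_test
from .decoding import PopulationDecoder, interpolate_curve
from .io import SessionBundle, config_hash, write_session
from .preprocess import bin_firing_rates
from .simulate import SimulationConfig, default_config, generate_session
from .subspace import build_subspace_model, class_separation_score, project_trajectories
from .task import trials_to_frame

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dmsdecode.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters for a full pipeline run."""

    simulation: SimulationConfig | None = None
    n_sessions: int = 2
    window_ms: float = 150.0
    stim_step_ms: float = 50.0
    choice_step_ms: float = 10.0
    n_folds: int = 20
    shrinkage: float = 0.1
    interp_resolution_ms: float = 2.0
    t_range_ms: tuple[float, float] = (2300.0, 3000.0)
    cross_t_ms: float = 2900.0
    rt_exclude_ms: float = 400.0
    t_ref_ms: float = 2700.0
    persistence_ms: float = 50.0
    save_sessions: bool = False


def _stage(name: str):
    """Decorate a closure so failures carry the stage name."""
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed: {exc}; "
                    f"re-run with the same config and seed to reproduce"
                ) from exc
        return run
    return wrap


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path = "results",
    seed: int = 0,
) -> dict:
    """Run the whole analysis and write results under ``out_dir``.

    Returns the summary dictionary (also written to ``summary.json``).
    Deterministic: a fixed config and seed give byte-identical summaries.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation or default_config(seed=seed)

    caught: list[str] = []

    @_stage("simulate")
    def simulate():
        sessions = []
        for s in range(cfg.n_sessions):
            sess_cfg = dataclasses.replace(sim, seed=int(sim.seed) + s).resolve()
            events, trials = generate_session(sess_cfg)
            sessions.append((sess_cfg, events, trials))
            log.info("session %d: %d trials, %d spikes", s, len(trials), len(events))
        return sessions

    sessions = simulate()

    if cfg.save_sessions:
        for s, (sess_cfg, events, trials) in enumerate(sessions):
            bundle = SessionBundle(
                session_id=f"session{s:02d}",
                events=events,
                trials=trials_to_frame(trials),
                n_channels=sess_cfg.n_channels,
                provenance={
                    "generator": "dmsdecode.simulate",
                    "config_hash": config_hash(sess_cfg),
                    "test_max_ms": sess_cfg.test_max_ms,
                    "post_response_ms": sess_cfg.post_response_ms,
                },
            )
            write_session(bundle, out / f"session{s:02d}", format="csv")

    @_stage("decode")
    def decode(target: str, step_ms: float):
        tensors, labels = [], []
        for sess_cfg, events, trials in sessions:
            tf = trials_to_frame(trials)
            tf = tf[tf["correct"]].reset_index(drop=True)
            tensor = bin_firing_rates(
                events, tf, window_ms=cfg.window_ms, step_ms=step_ms,
                t_range_ms=cfg.t_range_ms, n_channels=sess_cfg.n_channels,
            )
            tensors.append(tensor)
            labels.append(
                tf["test_stim" if target == "stimulus" else "trial_type"].to_numpy()
            )
        decoder = PopulationDecoder(
            tensors, labels, n_folds=cfg.n_folds, shrinkage=cfg.shrinkage
        )
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            curve = decoder.fit(seed=seed)
        caught.extend(f"{target}: {w.message}" for w in wlist)
        return curve

    stim_curve = decode("stimulus", cfg.stim_step_ms)
    choice_curve = decode("choice", cfg.choice_step_ms)
    stim_fine = interpolate_curve(stim_curve, cfg.interp_resolution_ms)
    choice_fine = interpolate_curve(choice_curve, cfg.interp_resolution_ms)

    test_onset = sessions[0][0].test_onset_ms
    for name, curve in (("stimulus", stim_curve), ("choice", choice_curve)):
        curve.to_frame().to_csv(out / f"decoding_{name}.csv", index=False)

    def _curve_summary(curve, fine):
        mean = fine.mean_accuracy
        peak = int(np.argmax(mean))
        entry = {
            "chance_level": round(curve.chance_level, 6),
            "peak_accuracy": round(float(mean[peak]), 6),
            "peak_time_ms": float(fine.times_ms[peak]),
            "latency_ms": fine.latency_of_chance_crossing(
                test_onset_ms=test_onset, persistence_ms=cfg.persistence_ms
            ),
        }
        if curve.n_sessions >= 2:
            t_at = min(2700.0, curve.times_ms[-1])
            t_stat, p, n = curve.vs_chance_test(t_at)
            entry["t_test_at_2700"] = {
                "t": round(t_stat, 6), "p": round(p, 8), "n_sessions": n,
            }
        return entry

    @_stage("crosstest")
    def crosstest():
        accs_c, accs_e = [], []
        for s, (sess_cfg, events, trials) in enumerate(sessions):
            tf = trials_to_frame(trials)
            tensor = bin_firing_rates(
                events, tf, window_ms=cfg.window_ms, step_ms=cfg.stim_step_ms,
                t_range_ms=cfg.t_range_ms, n_channels=sess_cfg.n_channels,
            )
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                res = cross_condition_test(
                    tensor, tf, t_ms=cfg.cross_t_ms, rt_exclude_ms=cfg.rt_exclude_ms,
                    n_folds=cfg.n_folds, seed=seed + s, shrinkage=cfg.shrinkage,
                )
            caught.extend(f"crosstest session {s}: {w.message}" for w in wlist)
            accs_c.append(res.accuracy_correct)
            accs_e.append(res.accuracy_error)
        return {
            "t_ms": cfg.cross_t_ms,
            "rt_exclude_ms": cfg.rt_exclude_ms,
            "accuracy_correct": round(float(np.mean(accs_c)), 6),
            "accuracy_error": round(float(np.mean(accs_e)), 6),
            "per_session_correct": [round(a, 6) for a in accs_c],
            "per_session_error": [round(a, 6) for a in accs_e],
        }

    @_stage("subspace")
    def subspaces():
        sess_cfg, events, trials = sessions[0]
        tf = trials_to_frame(trials)
        tfc = tf[tf["correct"]].reset_index(drop=True)
        tensor = bin_firing_rates(
            events, tfc, window_ms=cfg.window_ms, step_ms=cfg.stim_step_ms,
            t_range_ms=cfg.t_range_ms, n_channels=sess_cfg.n_channels,
        )
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            model = build_subspace_model(
                tensor, tfc, t_ref_ms=cfg.t_ref_ms, shrinkage=cfg.shrinkage, seed=seed
            )
        caught.extend(f"subspace: {w.message}" for w in wlist)
        pts = model.project(tensor.at_time(cfg.t_ref_ms))
        sil_stim = class_separation_score(pts[:, :2], tfc["test_stim"].to_numpy())
        sil_dec = class_separation_score(pts[:, :2], tfc["trial_type"].to_numpy())
        traj = project_trajectories(tensor, model)
        np.save(out / "trajectories.npy", traj)
        np.savetxt(out / "stim_projection.csv", model.stim_projection, delimiter=",")
        np.savetxt(out / "decision_projection.csv", model.decision_projection, delimiter=",")
        return {
            "t_ref_ms": float(model.t_ref_ms),
            "decision_stimulus_angle_deg": round(float(model.principal_angles_deg()[0]), 4),
            "silhouette_stimulus": round(sil_stim, 6),
            "silhouette_decision": round(sil_dec, 6),
        }

    summary = {
        "package_version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(sim),
        "n_sessions": cfg.n_sessions,
        "n_trials_per_session": sim.n_trials,
        "parameters": {
            "window_ms": cfg.window_ms,
            "stim_step_ms": cfg.stim_step_ms,
            "choice_step_ms": cfg.choice_step_ms,
            "n_folds": cfg.n_folds,
            "shrinkage": cfg.shrinkage,
            "interp_resolution_ms": cfg.interp_resolution_ms,
            "cross_t_ms": cfg.cross_t_ms,
            "rt_exclude_ms": cfg.rt_exclude_ms,
            "t_ref_ms": cfg.t_ref_ms,
        },
        "stimulus_decoding": _curve_summary(stim_curve, stim_fine),
        "choice_decoding": _curve_summary(choice_curve, choice_fine),
        "cross_condition": crosstest(),
        "subspace": subspaces(),
        "warnings": caught,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
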