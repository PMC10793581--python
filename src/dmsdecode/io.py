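"""Session bundles on disk: CSV directories and HDF5 files.

A session is a pair of tables — spike events ``(trial_id, channel,
spike_time_ms)`` and trial records — plus acquisition metadata and
provenance.  The CSV layout is a directory with ``events.csv``,
``trials.csv`` and ``meta.json``; the HDF5 layout is one file with an
``events`` and a ``trials`` group and metadata in root attributes.  Both
round-trip losslessly and are validated on load.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import SimulationConfig
from .task import EVENT_COLUMNS, TRIAL_COLUMNS, trial_end_ms, trials_from_frame

__all__ = [
    "SessionBundle",
    "read_session",
    "write_session",
    "save_config",
    "load_config",
    "config_hash",
]

_TRIAL_DTYPES = {
    "trial_id": np.int64,
    "sample_stim": np.int64,
    "test_stim": np.int64,
    "trial_type": str,
    "choice": str,
    "correct": bool,
    "rt_ms": float,
}


@dataclass
class SessionBundle:
    """One session: events, trial records, and provenance."""

    session_id: str
    events: pd.DataFrame
    trials: pd.DataFrame
    n_channels: int
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "SessionBundle":
        for col in EVENT_COLUMNS:
            if col not in self.events.columns:
                raise ValueError(f"events table missing column {col!r}")
        for col in TRIAL_COLUMNS:
            if col not in self.trials.columns:
                raise ValueError(f"trials table missing column {col!r}")
        trial_ids = set(self.trials["trial_id"].tolist())
        if len(trial_ids) != len(self.trials):
            raise ValueError("duplicate trial ids in trial table")
        ev_ids = set(self.events["trial_id"].tolist())
        orphans = ev_ids - trial_ids
        if orphans:
            raise ValueError(f"events reference unknown trial ids: {sorted(orphans)[:5]}")
        ch = self.events["channel"].to_numpy()
        if len(ch) and (ch.min() < 0 or ch.max() >= self.n_channels):
            raise ValueError(
                f"channel indices must lie in [0, {self.n_channels}); "
                f"found [{ch.min()}, {ch.max()}]"
            )
        times = self.events["spike_time_ms"].to_numpy(dtype=float)
        if len(times) and (not np.all(np.isfinite(times)) or times.min() < 0):
            raise ValueError("spike times must be finite and non-negative")
        # Spike times must not exceed the recorded span of their trial.
        test_max = float(self.provenance.get("test_max_ms", 500.0))
        post = float(self.provenance.get("post_response_ms", 200.0))
        ends = {
            int(row.trial_id): trial_end_ms(row.rt_ms, test_max, post)
            for row in self.trials.itertuples(index=False)
        }
        if len(times):
            end_per_event = self.events["trial_id"].map(ends).to_numpy(dtype=float)
            bad = times > end_per_event + 1e-6
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"spike at {times[i]:.3f} ms exceeds end of trial "
                    f"{self.events['trial_id'].iloc[i]}"
                )
        # Re-validates all trial-record invariants.
        trials_from_frame(self.trials)
        return self

    def sorted(self) -> "SessionBundle":
        ev = self.events.sort_values(list(EVENT_COLUMNS), kind="mergesort", ignore_index=True)
        tr = self.trials.sort_values("trial_id", kind="mergesort", ignore_index=True)
        return SessionBundle(self.session_id, ev, tr, self.n_channels, dict(self.provenance))


def write_session(bundle: SessionBundle, path: str | Path, format: str = "csv") -> Path:
    """Write a bundle; CSV → directory, HDF5 → single file.

    Rows are written in deterministic (trial, channel, time) order, so
    rewriting a read bundle is byte-identical.
    """
    path = Path(path)
    bundle = bundle.sorted()
    meta = {
        "session_id": bundle.session_id,
        "n_channels": int(bundle.n_channels),
        "provenance": bundle.provenance,
    }
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        bundle.events.to_csv(path / "events.csv", index=False, float_format="%.6f")
        bundle.trials.to_csv(path / "trials.csv", index=False, float_format="%.6f")
        (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            g = f.create_group("events")
            g.create_dataset("trial_id", data=bundle.events["trial_id"].to_numpy(np.int64))
            g.create_dataset("channel", data=bundle.events["channel"].to_numpy(np.int64))
            g.create_dataset(
                "spike_time_ms",
                data=np.round(bundle.events["spike_time_ms"].to_numpy(float), 6),
            )
            g = f.create_group("trials")
            for col in TRIAL_COLUMNS:
                data = bundle.trials[col].to_numpy()
                if data.dtype == object or data.dtype.kind in "U":
                    data = data.astype(h5py.string_dtype())
                elif col == "rt_ms":
                    data = np.round(data.astype(float), 6)
                g.create_dataset(col, data=data)
            f.attrs["meta"] = json.dumps(meta, sort_keys=True)
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'hdf5')")
    return path


def read_session(path: str | Path, format: str | None = None) -> SessionBundle:
    """Load and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "hdf5"
    if format == "csv":
        for fname in ("events.csv", "trials.csv", "meta.json"):
            if not (path / fname).exists():
                raise ValueError(f"session directory {path} is missing {fname}")
        events = pd.read_csv(path / "events.csv")
        trials = pd.read_csv(path / "trials.csv")
        meta = json.loads((path / "meta.json").read_text())
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            events = pd.DataFrame(
                {
                    "trial_id": f["events/trial_id"][:],
                    "channel": f["events/channel"][:],
                    "spike_time_ms": f["events/spike_time_ms"][:],
                }
            )
            tdata = {}
            for col in TRIAL_COLUMNS:
                arr = f[f"trials/{col}"][:]
                if arr.dtype.kind in ("O", "S"):
                    arr = np.array([v.decode() if isinstance(v, bytes) else v for v in arr])
                tdata[col] = arr
            trials = pd.DataFrame(tdata)
            meta = json.loads(f.attrs["meta"])
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'hdf5')")

    for col, dtype in _TRIAL_DTYPES.items():
        if col not in trials.columns:
            raise ValueError(f"{path}: trials table missing column {col!r}")
        try:
            trials[col] = trials[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            bad = trials.index[0]
            raise ValueError(
                f"{path}: column {col!r} has invalid values (first row {bad}): {exc}"
            ) from None
    bundle = SessionBundle(
        session_id=str(meta["session_id"]),
        events=events,
        trials=trials,
        n_channels=int(meta["n_channels"]),
        provenance=dict(meta.get("provenance", {})),
    )
    try:
        return bundle.sorted().validate()
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# configuration files


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    for key in ("stim_gain", "decision_direction"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["schema_version"] = 1
    return d


def save_config(cfg: SimulationConfig, path: str | Path) -> Path:
    """Write a simulation config as JSON (TOML is accepted on read)."""
    path = Path(path)
    path.write_text(json.dumps(_config_dict(cfg), indent=2, sort_keys=True) + "\n")
    return path


def load_config(path: str | Path) -> SimulationConfig:
    """Read a simulation config from a JSON or TOML file."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    data.pop("schema_version", None)
    for key in ("stim_gain", "decision_direction"):
        if data.get(key) is not None:
            data[key] = np.asarray(data[key], dtype=float)
    try:
        return SimulationConfig(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid config field: {exc}") from None


def config_hash(cfg: SimulationConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(_config_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
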