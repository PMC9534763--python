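"""Readers and writers for the trial-aligned session container.

Two dialects are supported:

``hdf5``
    a single file with group ``/units`` (one dataset per column), ``/trials``
    (one dataset per column) and ``/spikes/<unit_id>/<trial_id>`` ragged spike
    arrays; root attributes ``delay_duration_s`` and ``dataset_name``.
``csv``
    a directory with ``units.csv``, ``trials.csv`` and ``spikes.csv``
    (columns ``unit_id, trial_id, time_s``), human-readable for small fixtures.
    The delay duration is recovered from ``delay_start_s``.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import (
    Correctness,
    InstructedType,
    PhotostimCondition,
    Response,
    SessionValidationError,
    Trial,
    TrialAlignedSession,
    Unit,
)

__all__ = ["read_session", "write_session"]

_UNIT_COLS = ["unit_id", "mouse_id", "session_id", "depth_um", "spike_width_ms"]
_TRIAL_COLS = [
    "trial_id",
    "instructed_type",
    "response",
    "correctness",
    "sample_start_s",
    "delay_start_s",
    "reaction_time_ms",
    "photostim_target",
    "photostim_epoch",
    "photostim_power_mW",
]


def _units_frame(session: TrialAlignedSession) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "mouse_id": [u.mouse_id for u in session.units],
            "session_id": [u.session_id for u in session.units],
            "depth_um": [u.depth_um for u in session.units],
            "spike_width_ms": [u.spike_width_ms for u in session.units],
        }
    )


def _trials_frame(session: TrialAlignedSession) -> pd.DataFrame:
    rows = []
    for t in session.trials:
        ps = t.photostim
        rows.append(
            {
                "trial_id": t.trial_id,
                "instructed_type": t.instructed_type.value,
                "response": t.response.value,
                "correctness": t.correctness.value,
                "sample_start_s": t.sample_start_s,
                "delay_start_s": t.delay_start_s,
                "reaction_time_ms": np.nan
                if t.reaction_time_ms is None
                else t.reaction_time_ms,
                "photostim_target": "" if ps is None else ps.target,
                "photostim_epoch": "" if ps is None else ps.epoch,
                "photostim_power_mW": 0.0 if ps is None else ps.power_mW,
            }
        )
    return pd.DataFrame(rows, columns=_TRIAL_COLS)


def _build_session(
    units_df: pd.DataFrame,
    trials_df: pd.DataFrame,
    spikes: dict[tuple[str, int], np.ndarray],
    delay_duration_s: float,
    name: str,
) -> TrialAlignedSession:
    for col in _UNIT_COLS:
        if col not in units_df.columns:
            raise SessionValidationError(f"units table missing column {col!r}")
    for col in _TRIAL_COLS[:6]:
        if col not in trials_df.columns:
            raise SessionValidationError(f"trials table missing column {col!r}")
    units = [
        Unit(
            unit_id=str(r.unit_id),
            mouse_id=str(r.mouse_id),
            session_id=str(r.session_id),
            depth_um=float(r.depth_um),
            spike_width_ms=float(r.spike_width_ms),
        )
        for r in units_df.itertuples()
    ]
    trials = []
    for r in trials_df.itertuples():
        target = getattr(r, "photostim_target", "")
        if target is None or (isinstance(target, float) and np.isnan(target)):
            target = ""
        target = str(target)
        ps = None
        if target:
            ps = PhotostimCondition(
                target=target,
                epoch=str(getattr(r, "photostim_epoch", "")),
                power_mW=float(getattr(r, "photostim_power_mW", 0.0)),
            )
        rt = getattr(r, "reaction_time_ms", np.nan)
        rt = None if rt is None or (isinstance(rt, float) and np.isnan(rt)) else float(rt)
        trials.append(
            Trial(
                trial_id=int(r.trial_id),
                instructed_type=InstructedType(str(r.instructed_type)),
                response=Response(str(r.response)),
                correctness=Correctness(str(r.correctness)),
                sample_start_s=float(r.sample_start_s),
                delay_start_s=float(r.delay_start_s),
                reaction_time_ms=rt,
                photostim=ps,
            )
        )
    delays = {round(-t.delay_start_s, 9) for t in trials}
    if len(delays) > 1:
        raise SessionValidationError(
            f"all trials must share delay_duration_s; found {sorted(delays)}"
        )
    return TrialAlignedSession(
        units=units,
        trials=trials,
        spikes=spikes,
        delay_duration_s=float(delay_duration_s),
        name=name,
    )


# ---------------------------------------------------------------------------
# HDF5 dialect
# ---------------------------------------------------------------------------

def _write_hdf5(session: TrialAlignedSession, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["delay_duration_s"] = session.delay_duration_s
        f.attrs["dataset_name"] = session.name
        gu = f.create_group("units")
        for col, values in _units_frame(session).items():
            data = values.to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            gu.create_dataset(col, data=data)
        gt = f.create_group("trials")
        for col, values in _trials_frame(session).items():
            data = values.to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            gt.create_dataset(col, data=data)
        gs = f.create_group("spikes")
        for (uid, tid), st in session.spikes.items():
            gs.require_group(uid).create_dataset(str(tid), data=np.asarray(st, float))


def _read_hdf5(path: Path) -> TrialAlignedSession:
    with h5py.File(path, "r") as f:
        if "delay_duration_s" not in f.attrs:
            raise SessionValidationError("missing root attribute 'delay_duration_s'")
        delay = float(f.attrs["delay_duration_s"])
        name = str(f.attrs.get("dataset_name", path.stem))

        def _table(group: str, cols: list[str]) -> pd.DataFrame:
            if group not in f:
                raise SessionValidationError(f"missing group '/{group}'")
            data = {}
            for col in f[group]:
                arr = f[group][col][()]
                if arr.dtype.kind == "S":
                    arr = arr.astype(str)
                data[col] = arr
            return pd.DataFrame(data)

        units_df = _table("units", _UNIT_COLS)
        trials_df = _table("trials", _TRIAL_COLS)
        spikes: dict[tuple[str, int], np.ndarray] = {}
        if "spikes" in f:
            for uid in f["spikes"]:
                for tid in f["spikes"][uid]:
                    spikes[(uid, int(tid))] = f["spikes"][uid][tid][()]
    return _build_session(units_df, trials_df, spikes, delay, name)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(session: TrialAlignedSession, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    _units_frame(session).to_csv(path / "units.csv", index=False)
    _trials_frame(session).to_csv(path / "trials.csv", index=False)
    rows = []
    for (uid, tid), st in session.spikes.items():
        for t in np.asarray(st, float):
            rows.append((uid, tid, t))
    pd.DataFrame(rows, columns=["unit_id", "trial_id", "time_s"]).to_csv(
        path / "spikes.csv", index=False
    )


def _read_csv(path: Path) -> TrialAlignedSession:
    for fname in ("units.csv", "trials.csv", "spikes.csv"):
        if not (path / fname).exists():
            raise SessionValidationError(f"csv session directory missing {fname}")
    units_df = pd.read_csv(path / "units.csv")
    trials_df = pd.read_csv(path / "trials.csv")
    if "delay_start_s" not in trials_df.columns:
        raise SessionValidationError("trials table missing column 'delay_start_s'")
    spikes_df = pd.read_csv(path / "spikes.csv")
    spikes: dict[tuple[str, int], np.ndarray] = {}
    if len(spikes_df):
        for (uid, tid), grp in spikes_df.groupby(["unit_id", "trial_id"], sort=False):
            spikes[(str(uid), int(tid))] = grp["time_s"].to_numpy(float)
    delay = float(-trials_df["delay_start_s"].iloc[0]) if len(trials_df) else 1.3
    return _build_session(units_df, trials_df, spikes, delay, path.name)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    if path.is_dir() or path.suffix == "":
        return "csv"
    return "hdf5"


def read_session(path: str | os.PathLike, dialect: str | None = None) -> TrialAlignedSession:
    """Read and validate a :class:`TrialAlignedSession` from disk."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "hdf5":
        return _read_hdf5(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_session(
    session: TrialAlignedSession, path: str | os.PathLike, dialect: str | None = None
) -> None:
    """Write a session; ``dialect`` is inferred from the path if omitted."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "hdf5":
        _write_hdf5(session, path)
    elif dialect == "csv":
        _write_csv(session, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
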