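"""Readers and writers for muscle parameter tables and gait trials.

Muscle parameters travel as a delimited table (CSV, one row per muscle) or
JSON; an importer for the musculoskeletal-model XML format used by common
simulation software extracts the Hill-model fields (name, max isometric
force, optimal fiber length, tendon slack length, pennation) from muscle
elements. Gait trials are written as tidy long-format CSV (time, channel,
name, value) with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .muscle import MuscleParams, MuscleTrajectory
from .stride import GaitTrial

__all__ = [
    "read_muscle_params",
    "write_muscle_params",
    "read_muscle_params_json",
    "read_opensim_muscles",
    "write_trial",
    "read_trial",
]

_CSV_COLUMNS = {
    "name": str, "f_iso_max": float, "l_opt": float, "l_tendon_slack": float,
    "alpha_opt": float, "v_max": float, "frac_slow": float, "mass": float,
    "tau_act": float, "tau_deact": float,
    "tendon_strain_iso": float, "tendon_stiffness_shape": float,
}
_REQUIRED = ("name", "f_iso_max", "l_opt", "l_tendon_slack")


def _params_from_record(rec: dict) -> MuscleParams:
    kwargs = {}
    for key in _CSV_COLUMNS:
        if key in rec and rec[key] is not None and not (
                isinstance(rec[key], float) and np.isnan(rec[key])):
            kwargs[key] = rec[key]
    return MuscleParams(**kwargs)


def read_muscle_params(path) -> list[MuscleParams]:
    """Read a muscle parameter CSV (one row per muscle).

    Required columns: ``name, f_iso_max, l_opt, l_tendon_slack``; all other
    :class:`~gaitbench.muscle.MuscleParams` fields are optional and default
    when absent or empty.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"muscle parameter table missing columns: {missing}")
    return [_params_from_record(rec) for rec in df.to_dict(orient="records")]


def write_muscle_params(muscles: list[MuscleParams], path) -> None:
    rows = []
    for m in muscles:
        rows.append({k: getattr(m, k) for k in _CSV_COLUMNS})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_muscle_params_json(path) -> list[MuscleParams]:
    """JSON alternative: a list of muscle-parameter objects."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise ValueError("expected a JSON list of muscle objects")
    return [_params_from_record(rec) for rec in data]


_OSIM_FIELDS = {
    "max_isometric_force": "f_iso_max",
    "optimal_fiber_length": "l_opt",
    "tendon_slack_length": "l_tendon_slack",
    "pennation_angle_at_optimal": "alpha_opt",
    "pennation_angle": "alpha_opt",  # older models
}


def read_opensim_muscles(path) -> list[MuscleParams]:
    """Extract Hill-model parameters from a musculoskeletal-model XML file.

    Scans the model for elements whose tag ends in ``Muscle`` and reads the
    standard property names (``max_isometric_force``,
    ``optimal_fiber_length``, ``tendon_slack_length``,
    ``pennation_angle_at_optimal``). Only the fields this package uses are
    imported; other model content is ignored.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    muscles = []
    for el in root.iter():
        if not el.tag.endswith("Muscle"):
            continue
        name = el.get("name")
        if not name:
            continue
        fields: dict = {"name": name}
        for child in el:
            key = _OSIM_FIELDS.get(child.tag)
            if key is not None and child.text is not None and key not in fields:
                fields[key] = float(child.text)
        if all(k in fields for k in _REQUIRED):
            muscles.append(MuscleParams(**fields))
    if not muscles:
        raise ValueError(f"no complete muscle definitions found in {path}")
    return muscles


# ---------------------------------------------------------------------------
# Gait trial I/O (tidy long CSV + JSON sidecar)
# ---------------------------------------------------------------------------

_MUSCLE_CHANNELS = ("e", "a", "l_fiber_norm", "v_fiber_norm",
                    "f_fiber", "f_tendon", "p_fiber")
_TABLE_CHANNELS = ("q", "qdot", "qddot", "tau", "e_arms", "u_slack",
                   "contact_force", "contact_velocity")


def write_trial(trial: GaitTrial, csv_path, sidecar_path=None) -> None:
    """Write a trial as long-format CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path is not None \
        else csv_path.with_suffix(".json")
    frames = []
    for mname, traj in trial.muscles.items():
        for ch in _MUSCLE_CHANNELS:
            frames.append(pd.DataFrame({
                "time": trial.t, "channel": f"muscle.{ch}", "name": mname,
                "value": getattr(traj, ch)}))
    for ch in _TABLE_CHANNELS:
        df = getattr(trial, ch)
        if df is None:
            continue
        for col in df.columns:
            frames.append(pd.DataFrame({
                "time": trial.t, "channel": ch, "name": col,
                "value": df[col].to_numpy()}))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)

    meta = {
        "stride_time": trial.stride_time,
        "speed": trial.speed,
        "body_mass": trial.body_mass,
        "condition": trial.condition,
        "muscles": {
            name: (None if traj.params is None else {
                k: getattr(traj.params, k)
                for k in _CSV_COLUMNS if hasattr(traj.params, k)})
            for name, traj in trial.muscles.items()
        },
        "periodic": {name: bool(traj.periodic)
                     for name, traj in trial.muscles.items()},
    }
    sidecar_path.write_text(json.dumps(meta, indent=1))


def read_trial(csv_path, sidecar_path=None) -> GaitTrial:
    """Read a trial written by :func:`write_trial`."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path is not None \
        else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(csv_path)
    t = np.sort(df["time"].unique())

    muscles = {}
    mdf = df[df["channel"].str.startswith("muscle.")]
    for name, g in mdf.groupby("name"):
        channels = {}
        for ch in _MUSCLE_CHANNELS:
            sub = g[g["channel"] == f"muscle.{ch}"].sort_values("time")
            channels[ch] = sub["value"].to_numpy(dtype=float)
        pinfo = meta["muscles"].get(name)
        params = MuscleParams(**pinfo) if pinfo else None
        muscles[name] = MuscleTrajectory(
            t=t, stride_time=meta["stride_time"],
            periodic=bool(meta.get("periodic", {}).get(name, False)),
            params=params, **channels)

    tables = {}
    for ch in _TABLE_CHANNELS:
        sub = df[df["channel"] == ch]
        if sub.empty:
            tables[ch] = None
            continue
        tables[ch] = sub.pivot(index="time", columns="name", values="value")
    return GaitTrial(t=t, muscles=muscles, stride_time=meta["stride_time"],
                     speed=meta["speed"], body_mass=meta.get("body_mass", 62.0),
                     condition=meta.get("condition", {}), **tables)
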