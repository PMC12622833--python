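"""Dimensionless gait normalization and simulation-vs-experiment comparison.

Outcomes measured on subjects of different size are made comparable by
dynamic (Froude-style) scaling with body mass ``m``, leg length ``l`` and
gravity ``g``: frequencies scale with ``sqrt(g/l)``, joint moments with
``m*g*l``, ground reaction forces with ``m*g`` and (metabolic) powers with
``m * g^1.5 * l^0.5``. Changes from a reference condition are then compared
between simulation and experiment with a linear least-squares fit (R^2,
RMSE, slope), the slope quantifying over/underestimation of the changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Anthropometry",
    "MODEL_ANTHROPOMETRY",
    "ConditionDataset",
    "to_dimensionless",
    "from_dimensionless",
    "rescale_to_model",
    "change_from_reference",
    "compare",
]

#: Leg length as a fraction of stature when leg length is not given directly.
LEG_LENGTH_STATURE_RATIO = 0.53


@dataclass(frozen=True)
class Anthropometry:
    """Body mass (kg), leg length (m), stature (m), gravity (m/s^2)."""

    body_mass: float
    leg_length: float | None = None
    stature: float | None = None
    g: float = 9.81

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.g <= 0:
            raise ValueError("body_mass and g must be > 0")
        if self.leg_length is None and self.stature is None:
            raise ValueError("give leg_length or stature")
        for v in (self.leg_length, self.stature):
            if v is not None and v <= 0:
                raise ValueError("lengths must be > 0")

    @property
    def l(self) -> float:
        if self.leg_length is not None:
            return self.leg_length
        return LEG_LENGTH_STATURE_RATIO * self.stature


#: Default simulation-model anthropometry: 62 kg, 1.70 m stature.
MODEL_ANTHROPOMETRY = Anthropometry(body_mass=62.0, stature=1.70)

_KINDS = ("frequency", "moment", "grf", "power")


def _factor(kind: str, anthro: Anthropometry) -> float:
    m, l, g = anthro.body_mass, anthro.l, anthro.g
    if kind == "frequency":
        return math.sqrt(g / l)
    if kind == "moment":
        return m * g * l
    if kind == "grf":
        return m * g
    if kind == "power":
        return m * g ** 1.5 * l ** 0.5
    raise ValueError(f"unknown kind {kind!r}; expected one of {_KINDS}")


def to_dimensionless(value, kind: str, anthro: Anthropometry):
    """Normalize a value to dimensionless units for the given anthropometry."""
    return np.asarray(value, dtype=float) / _factor(kind, anthro) \
        if np.ndim(value) else value / _factor(kind, anthro)


def from_dimensionless(value, kind: str, anthro: Anthropometry):
    """Invert :func:`to_dimensionless`."""
    return np.asarray(value, dtype=float) * _factor(kind, anthro) \
        if np.ndim(value) else value * _factor(kind, anthro)


def rescale_to_model(value, kind: str, anthro_source: Anthropometry,
                     anthro_model: Anthropometry = MODEL_ANTHROPOMETRY):
    """Re-express a value measured on one subject in model units.

    Normalizes with the source anthropometry and de-normalizes with the
    model's, i.e. multiplies by the ratio of normalization factors.
    """
    return from_dimensionless(to_dimensionless(value, kind, anthro_source),
                              kind, anthro_model)


class ConditionDataset:
    """Condition-level scalar outcomes with reference-condition bookkeeping.

    Wraps a tidy DataFrame with columns ``condition``, ``speed``, ``slope``,
    ``added_mass``, ``outcome``, ``value``, ``source`` (simulation /
    experiment / study label). ``(condition, outcome, source)`` must be
    unique. ``reference`` names the reference condition for
    change-from-reference deltas.
    """

    COLUMNS = ("condition", "speed", "slope", "added_mass",
               "outcome", "value", "source")

    def __init__(self, df: pd.DataFrame, reference: str | None = None):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        dup = df.duplicated(subset=["condition", "outcome", "source"])
        if dup.any():
            raise ValueError("(condition, outcome, source) rows must be unique")
        self.df = df.reset_index(drop=True)
        self.reference = reference

    @classmethod
    def from_csv(cls, path, reference: str | None = None) -> "ConditionDataset":
        return cls(pd.read_csv(path), reference=reference)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def change_from_reference(data: ConditionDataset,
                          reference: str | None = None,
                          mode: str = "global") -> pd.DataFrame:
    """Delta table: outcome value minus its reference-condition value.

    ``mode='global'`` subtracts the single named reference condition per
    (outcome, source) group. ``mode='per_speed'`` — the added-mass rule —
    subtracts, within each (outcome, source, speed) group, the row with zero
    added mass at the same speed.
    """
    ref = reference if reference is not None else data.reference
    df = data.df
    rows = []
    if mode == "global":
        if ref is None:
            raise ValueError("global mode needs a reference condition id")
        for (outcome, source), g in df.groupby(["outcome", "source"]):
            ref_rows = g[g["condition"] == ref]
            if ref_rows.empty:
                raise ValueError(
                    f"missing reference condition {ref!r} for outcome={outcome!r}, "
                    f"source={source!r}")
            ref_val = float(ref_rows["value"].iloc[0])
            out = g.copy()
            out["delta"] = out["value"] - ref_val
            rows.append(out)
    elif mode == "per_speed":
        for (outcome, source, speed), g in df.groupby(["outcome", "source", "speed"]):
            ref_rows = g[g["added_mass"] == 0]
            if ref_rows.empty:
                raise ValueError(
                    f"missing zero-added-mass reference at speed {speed} for "
                    f"outcome={outcome!r}, source={source!r}")
            ref_val = float(ref_rows["value"].iloc[0])
            out = g.copy()
            out["delta"] = out["value"] - ref_val
            rows.append(out)
    else:
        raise ValueError("mode must be 'global' or 'per_speed'")
    return pd.concat(rows, ignore_index=True)


def compare(sim_deltas, exp_deltas, through_origin: bool = False) -> dict:
    """Agreement statistics between simulated and measured condition deltas.

    Ordinary least squares of simulated on experimental deltas (intercept
    included unless ``through_origin``): returns ``slope`` (with standard
    error), ``r2``, paired-difference ``rmse`` (primary; sim - exp), fit-
    residual ``rmse_fit``, and ``pct_misestimate = (1 - slope) * 100``
    (positive = underestimation of the changes).
    """
    sim = np.asarray(sim_deltas, dtype=float)
    exp = np.asarray(exp_deltas, dtype=float)
    if sim.shape != exp.shape or sim.ndim != 1:
        raise ValueError("sim and exp deltas must be paired 1-D arrays")
    if sim.size < 2:
        raise ValueError("need at least two paired deltas")
    if np.ptp(exp) == 0:
        raise ValueError("experimental deltas have zero variance")

    X = exp[:, None] if through_origin else sm.add_constant(exp)
    fit = sm.OLS(sim, X).fit()
    slope = float(fit.params[-1])
    slope_se = float(fit.bse[-1])
    resid = fit.resid
    return {
        "slope": slope,
        "slope_se": slope_se,
        "intercept": 0.0 if through_origin else float(fit.params[0]),
        "r2": float(fit.rsquared),
        "rmse": float(np.sqrt(np.mean((sim - exp) ** 2))),
        "rmse_fit": float(np.sqrt(np.mean(resid ** 2))),
        "pct_misestimate": (1.0 - slope) * 100.0,
        "n": int(sim.size),
    }
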