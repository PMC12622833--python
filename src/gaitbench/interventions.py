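"""Mechanical intervention models: added point mass, slope, constraints.

World frame convention used package-wide: x forward, y up, z to the right;
positive grade = uphill. Added mass is a true point mass rigidly attached to
a segment (segment mass, center of mass and inertia are updated by composite-
body rules); slope is modeled by rotating the gravity vector about the
mediolateral (z) axis; crouch and imposed-speed conditions are carried as
validated constraint records for downstream solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentProps",
    "ConstraintRecord",
    "add_point_mass",
    "gravity_for_slope",
    "make_constraint",
    "GRAVITY",
]

GRAVITY = 9.81


@dataclass(frozen=True)
class SegmentProps:
    """Rigid-segment inertial properties in the segment frame.

    ``com`` is the center-of-mass position (m, 3-vector); ``inertia`` the
    3x3 inertia tensor about the COM (kg*m^2), symmetric positive
    semi-definite.
    """

    mass: float
    com: tuple[float, float, float]
    inertia: tuple  # 3x3 nested tuple

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("segment mass must be > 0")
        I = np.asarray(self.inertia, dtype=float)
        if I.shape != (3, 3):
            raise ValueError("inertia must be 3x3")
        if not np.allclose(I, I.T, atol=1e-9):
            raise ValueError("inertia must be symmetric")
        eig = np.linalg.eigvalsh(0.5 * (I + I.T))
        if np.min(eig) < -1e-9:
            raise ValueError("inertia must be positive semi-definite")

    @property
    def com_arr(self) -> np.ndarray:
        return np.asarray(self.com, dtype=float)

    @property
    def inertia_arr(self) -> np.ndarray:
        return np.asarray(self.inertia, dtype=float)


def _parallel_axis(I_com: np.ndarray, mass: float, r: np.ndarray) -> np.ndarray:
    """Inertia about a point offset ``r`` from the COM (parallel-axis theorem)."""
    return I_com + mass * (float(r @ r) * np.eye(3) - np.outer(r, r))


def add_point_mass(seg: SegmentProps, m_add: float,
                   r: tuple[float, float, float]) -> SegmentProps:
    """Rigidly attach a point mass at ``r`` (segment frame, m).

    The point mass carries no inertia of its own. The combined COM is the
    mass-weighted average and the combined inertia about the new COM follows
    from parallel-axis transfer of both the original body and the point
    mass, so successive attachments commute.
    """
    if m_add < 0:
        raise ValueError("added mass must be >= 0")
    if m_add == 0:
        return seg
    r = np.asarray(r, dtype=float)
    m_new = seg.mass + m_add
    com_new = (seg.mass * seg.com_arr + m_add * r) / m_new
    I_new = (_parallel_axis(seg.inertia_arr, seg.mass, seg.com_arr - com_new)
             + _parallel_axis(np.zeros((3, 3)), m_add, r - com_new))
    return SegmentProps(mass=m_new, com=tuple(com_new),
                        inertia=tuple(map(tuple, I_new)))


def gravity_for_slope(grade_percent: float, g: float = GRAVITY) -> np.ndarray:
    """Gravity vector (m/s^2, world frame) for walking on a grade.

    Uphill walking on grade ``p`` % is equivalent to level walking with the
    gravity vector rotated by ``theta = atan(p/100)`` about the mediolateral
    axis: a forward gravity component ``g*sin(theta)`` opposing progression.
    Grade 0 gives ``(0, -g, 0)``; the magnitude is preserved for any grade.
    """
    if not math.isfinite(grade_percent):
        raise ValueError("grade must be finite")
    theta = math.atan(grade_percent / 100.0)
    return np.array([g * math.sin(theta), -g * math.cos(theta), 0.0])


_CONSTRAINT_KINDS = ("crouch_ceiling", "imposed_speed")


@dataclass(frozen=True)
class ConstraintRecord:
    """Validated task-constraint record (bookkeeping only; no solver here).

    ``crouch_ceiling``: maximal pelvis height capped at ``parameter`` times
    the unconstrained maximum (fraction in (0, 1]).
    ``imposed_speed``: average forward pelvis speed fixed at ``parameter``
    m/s (> 0).
    """

    kind: str
    parameter: float


def make_constraint(kind: str, parameter: float) -> ConstraintRecord:
    """Build and validate a constraint record."""
    if kind not in _CONSTRAINT_KINDS:
        raise ValueError(f"unknown constraint kind {kind!r}; "
                         f"expected one of {_CONSTRAINT_KINDS}")
    if kind == "crouch_ceiling" and not 0.0 < parameter <= 1.0:
        raise ValueError("crouch ceiling fraction must be in (0, 1]")
    if kind == "imposed_speed" and not parameter > 0:
        raise ValueError("imposed speed must be > 0")
    return ConstraintRecord(kind=kind, parameter=float(parameter))
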