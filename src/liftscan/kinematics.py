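"""Closed-form motion timing for a microscope stage axis.

A crossed x,y stage executes point-to-point moves under a constant-
acceleration profile: accelerate at ``a`` up to at most ``v_max``, cruise,
then decelerate symmetrically to a standstill.  When the move is shorter
than twice the acceleration distance the cruise phase vanishes and the
profile is triangular with peak velocity ``sqrt(a * L)``.

The demonstrator stage reaches 120 mm/s; its acceleration is derated to
100 mm/s**2 to limit sloshing of the culture medium, which on a 120 mm
line caps the actually reached velocity at about 109.5 mm/s.

Units
-----
Lengths in mm, times in s, velocities in mm/s, accelerations in mm/s**2.
Micrometres appear only at module interfaces (e.g. in-flight displacement)
and are converted on entry/exit.  All functions accept scalars or NumPy
arrays and return the matching kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StageKinematics",
    "accel_distance",
    "peak_velocity",
    "move_time_1d",
    "move_time_2d",
    "time_at_distance",
    "inflight_displacement",
]


@dataclass(frozen=True)
class StageKinematics:
    """Kinematic limits of one stage axis.

    Parameters
    ----------
    v_max : float
        Maximum commanded velocity, mm/s.  Must be positive.
    a : float
        Constant acceleration magnitude, mm/s**2.  Must be positive.
    """

    v_max: float
    a: float

    def __post_init__(self) -> None:
        if not (self.v_max > 0 and np.isfinite(self.v_max)):
            raise ValueError(f"v_max must be positive and finite, got {self.v_max!r}")
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError(f"a must be positive and finite, got {self.a!r}")


def _as_nonneg(distance, name: str = "distance") -> np.ndarray:
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError(f"{name} must be non-negative")
    return d


def _ret(x: np.ndarray):
    # return a plain float for 0-d input
    return float(x) if x.ndim == 0 else x


def accel_distance(kin: StageKinematics) -> float:
    """Distance needed to accelerate from rest to ``v_max`` (mm).

    Equals ``v_max**2 / (2 a)``; the same distance is needed to brake.
    """
    return 0.5 * kin.v_max**2 / kin.a


def peak_velocity(distance, kin: StageKinematics):
    """Velocity actually reached on a move of the given length (mm/s).

    ``min(v_max, sqrt(a * L))``: short moves turn around before the cap
    is reached.
    """
    d = _as_nonneg(distance)
    return _ret(np.minimum(kin.v_max, np.sqrt(kin.a * d)))


def move_time_1d(distance, kin: StageKinematics):
    """Time to traverse ``distance`` mm from standstill to standstill.

    For ``L >= 2 * accel_distance`` the trapezoidal closed form
    ``2 v_max / a + (L - 2 L_accel) / v_max`` applies; shorter moves use
    the triangular profile ``2 sqrt(L / a)``.  The two branches agree at
    the threshold, so the function is continuous and strictly increasing.
    """
    d = _as_nonneg(distance)
    l2 = 2.0 * accel_distance(kin)
    with np.errstate(invalid="ignore"):
        trap = 2.0 * kin.v_max / kin.a + (d - l2) / kin.v_max
        tri = 2.0 * np.sqrt(d / kin.a)
    return _ret(np.where(d >= l2, trap, tri))


def move_time_2d(dx, dy, kin: StageKinematics):
    """Time for a simultaneous two-axis point-to-point move (s).

    Both axes start together and each follows its own 1-D profile, so the
    move completes when the slower axis does: ``max`` of the per-axis
    times.  Signs of the deltas are irrelevant.
    """
    tx = move_time_1d(np.abs(np.asarray(dx, dtype=float)), kin)
    ty = move_time_1d(np.abs(np.asarray(dy, dtype=float)), kin)
    out = np.maximum(tx, ty)
    return float(out) if np.ndim(out) == 0 else out


def time_at_distance(s, total_distance: float, kin: StageKinematics):
    """Time at which a move of ``total_distance`` mm has covered ``s`` mm.

    Inverse of the position profile of the accelerate-(cruise)-decelerate
    move; strictly increasing in ``s`` with ``t(0) = 0`` and
    ``t(L) = move_time_1d(L)``.

    Raises
    ------
    ValueError
        If any ``s`` lies outside ``[0, total_distance]``.
    """
    L = float(total_distance)
    if L < 0:
        raise ValueError("total_distance must be non-negative")
    sa = np.asarray(s, dtype=float)
    tol = 1e-9 * max(L, 1.0)
    if np.any(sa < -tol) or np.any(sa > L + tol):
        raise ValueError("position lies outside the move extent")
    sa = np.clip(sa, 0.0, L)
    if L == 0.0:
        return _ret(np.zeros_like(sa))
    vp = float(peak_velocity(L, kin))
    l_acc = 0.5 * vp**2 / kin.a
    t_acc = vp / kin.a
    t_total = float(move_time_1d(L, kin))
    with np.errstate(invalid="ignore"):
        t = np.select(
            [sa <= l_acc, sa <= L - l_acc],
            [np.sqrt(2.0 * sa / kin.a), t_acc + (sa - l_acc) / vp],
            default=t_total - np.sqrt(2.0 * np.clip(L - sa, 0.0, None) / kin.a),
        )
    return _ret(t)


def inflight_displacement(v, event_duration):
    """Sample displacement during a transfer event, in micrometres.

    The stage keeps moving while a LIFT jet forms; at cruise velocity
    ``v`` (mm/s) over an event of ``event_duration`` seconds the sample
    travels ``v * duration`` mm, returned in um (e.g. 120 mm/s over
    200 us -> 24 um).
    """
    va = _as_nonneg(v, "velocity")
    da = _as_nonneg(event_duration, "event_duration")
    return _ret(va * da * 1e3)
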