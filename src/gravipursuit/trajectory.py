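"""Target kinematics: parabolic trajectories with linear air drag.

The stimulus is a tennis-ball-sized target launched on a parabola in the
fronto-parallel plane at a fixed depth.  Air resistance is modelled as a
force proportional to velocity (coefficient ``c``), which admits the
closed-form solution

    x(t) = x0 + (v_xi / k) (1 - e^{-k t})
    y(t) = y0 + s * [ ((v_yi + g/k) / k) (1 - e^{-k t}) - (g/k) t ]

with ``k = c/m`` and ``s`` the sign of the gravity multiplier: positive
gravities launch the target upward from 0.5 m and pull it back down;
the -1 g condition is the mirror image, launched downward from 3.5 m
with "gravity" pulling upward toward an elongated lamp on the ceiling.

The module also evaluates the drag-free earth-gravity extrapolation used
to predict when an occluded target reaches the coincidence height: the
positive root of  d = (g_e / 2) t^2 + v t  for remaining distance ``d``
and last seen vertical velocity ``v`` (downward positive), with
``g_e = 9.81 m/s^2`` regardless of the gravity that actually governs the
stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

G_EARTH = 9.81  # m/s^2, the magnitude behind every gravity multiplier

#: start heights (m): positive multipliers launch upward from just above
#: the floor; -1 g launches downward from near the ceiling.
START_Y_UP = 0.5
START_Y_DOWN = 3.5

Z_PLANE = -6.15  # m, depth of the stimulus plane (negative = in front)

ROOT_TOL = 1e-12  # s, bracketed root tolerance for flight-time searches
MAX_FLIGHT = 10.0  # s, upper bracket for any root search


class TrajectoryError(ValueError):
    """Invalid trajectory parameters or query."""


@dataclass(frozen=True)
class TrajectoryParams:
    """Physical parameters of one target trajectory.

    ``gravity_mult`` is a signed multiple of earth gravity; its magnitude
    sets the gravity strength and its sign selects the upright (positive)
    or inverted (-1) geometry.  ``start_x`` places the launch point so
    the apex (or valley) lies at x = 0.
    """

    gravity_mult: float
    v_xi: float  # initial horizontal velocity, m/s (rightward)
    v_yi: float  # initial vertical speed, m/s (magnitude)
    m: float = 0.057  # target mass, kg
    c: float = 0.005  # linear drag coefficient, kg/s
    start_x: float = 0.0
    start_y: float = START_Y_UP
    z_plane: float = Z_PLANE

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise TrajectoryError(f"mass must be positive, got {self.m}")
        if self.c < 0:
            raise TrajectoryError(f"drag coefficient must be >= 0, got {self.c}")
        if self.gravity_mult == 0:
            raise TrajectoryError("gravity multiplier must be nonzero")
        if self.v_xi <= 0 or self.v_yi <= 0:
            raise TrajectoryError("initial speeds must be positive")

    @property
    def g(self) -> float:
        """Gravity magnitude, m/s^2."""
        return G_EARTH * abs(self.gravity_mult)

    @property
    def sign(self) -> float:
        """+1 for upright trajectories, -1 for the inverted geometry."""
        return 1.0 if self.gravity_mult > 0 else -1.0


@dataclass(frozen=True)
class KinematicState:
    """Target state at one instant (scene coordinates, up positive)."""

    t: float
    x: float
    y: float
    vx: float
    vy: float


@dataclass(frozen=True)
class TtcQuery:
    """Inputs to the earth-gravity extrapolation at occlusion onset.

    Coordinates are "toward coincidence": ``d_y`` is the remaining
    distance to the coincidence height (>= 0) and ``v_y_last`` the last
    seen vertical velocity with *away from coincidence* positive (i.e.
    up-positive for upright trajectories; the inverted geometry is
    queried in its mirrored frame).
    """

    v_y_last: float
    d_y: float
    g_earth: float = G_EARTH

    def __post_init__(self) -> None:
        if self.d_y < 0:
            raise TrajectoryError(f"remaining distance must be >= 0, got {self.d_y}")


def make_params(
    gravity_mult: float,
    v_xi: float,
    v_yi: float,
    m: float = 0.057,
    c: float = 0.005,
) -> TrajectoryParams:
    """Build trajectory parameters with the scene-centred launch point.

    The start height follows the sign rule and ``start_x`` is set to
    minus half the horizontal length covered up to the return time, so
    the vertical extremum sits at x = 0 (exactly so without drag).
    """
    start_y = START_Y_UP if gravity_mult > 0 else START_Y_DOWN
    base = TrajectoryParams(
        gravity_mult=gravity_mult, v_xi=v_xi, v_yi=v_yi, m=m, c=c,
        start_x=0.0, start_y=start_y,
    )
    T = return_time(base)
    length = position(base, T).x  # start_x = 0, so this is the span
    return replace(base, start_x=-length / 2.0)


@lru_cache(maxsize=512)
def _cached_params(gravity_mult: float, v_xi: float, v_yi: float,
                   m: float, c: float) -> TrajectoryParams:
    return make_params(gravity_mult, v_xi, v_yi, m=m, c=c)


def params_for(gravity_mult: float, v_xi: float, v_yi: float,
               m: float = 0.057, c: float = 0.005) -> TrajectoryParams:
    """Cached :func:`make_params` (conditions repeat heavily in a design)."""
    return _cached_params(float(gravity_mult), float(v_xi), float(v_yi),
                          float(m), float(c))


# ---------------------------------------------------------------------------
# closed-form kinematics
#
# The linear-drag solution is written with the entire functions
#   phi1(z) = (1 - e^-z)/z       -> 1    as z -> 0
#   phi2(z) = (z - (1 - e^-z))/z^2 -> 1/2 as z -> 0
# so that  x = x0 + v_xi t phi1(kt),  y-excursion = v_yi t phi1(kt)
#          - g t^2 phi2(kt),  vy = v_yi e^-kt - g t phi1(kt),
# which is algebraically identical to the usual exponential form but
# free of the g/k cancellation that destroys precision as c -> 0 (the
# ballistic limit, including c = 0 exactly, falls out of the series).

_SERIES_Z = 1e-4


def _phi1(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < _SERIES_Z
    zs = np.where(small, 0.0, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        exact = -np.expm1(-zs) / np.where(small, 1.0, zs)
    series = 1.0 - z / 2.0 + z**2 / 6.0 - z**3 / 24.0
    return np.where(small, series, exact)


def _phi2(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < _SERIES_Z
    zs = np.where(small, 1.0, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        exact = (zs + np.expm1(-zs)) / zs**2
    series = 0.5 - z / 6.0 + z**2 / 24.0 - z**3 / 120.0
    return np.where(small, series, exact)


def _vertical_excursion(p: TrajectoryParams, t):
    """Unsigned vertical displacement f(t) away from the start height."""
    t_arr = np.asarray(t, dtype=float)
    z = (p.c / p.m) * t_arr
    return p.v_yi * t_arr * _phi1(z) - p.g * t_arr**2 * _phi2(z)


def position(p: TrajectoryParams, t) -> KinematicState:
    """Target state at time ``t`` (scalar) or times (array).

    Evaluates the linear-drag closed form; ``c = 0`` reduces exactly to
    the ballistic solution.  For array input the fields of the returned
    state are arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise TrajectoryError("time must be >= 0")
    s = p.sign
    k = p.c / p.m
    z = k * t_arr
    phi1 = _phi1(z)
    x = p.start_x + p.v_xi * t_arr * phi1
    y = p.start_y + s * _vertical_excursion(p, t_arr)
    ex = np.exp(-z)
    vx = p.v_xi * ex
    vy = s * (p.v_yi * ex - p.g * t_arr * phi1)
    if np.isscalar(t) or t_arr.ndim == 0:
        return KinematicState(float(t_arr), float(x), float(y), float(vx), float(vy))
    return KinematicState(t_arr, x, y, vx, vy)


def speed(p: TrajectoryParams, t):
    """Tangential (total) target speed at ``t``, m/s."""
    st = position(p, t)
    return np.hypot(st.vx, st.vy)


def _peak_time(p: TrajectoryParams) -> float:
    """Time of the vertical extremum (vy = 0)."""
    if p.c == 0.0:
        return p.v_yi / p.g
    k = p.c / p.m
    return math.log1p(k * p.v_yi / p.g) / k


@lru_cache(maxsize=4096)
def _cached_return_time(p: TrajectoryParams) -> float:
    t_peak = _peak_time(p)
    f = lambda t: float(_vertical_excursion(p, t))
    hi = 2.0 * t_peak
    while f(hi) > 0:
        hi *= 1.5
        if hi > MAX_FLIGHT:
            raise TrajectoryError("no return to start height within bracket")
    return float(brentq(f, t_peak, hi, xtol=ROOT_TOL))


def return_time(p: TrajectoryParams) -> float:
    """Smallest t > 0 at which the target returns to the start height."""
    return _cached_return_time(p)


def coincidence_x(p: TrajectoryParams) -> float:
    """x position at the return time — where the target meets the table/lamp."""
    return position(p, return_time(p)).x


SHORT_OCCLUSION = (0.20, 0.25)
LONG_OCCLUSION = (0.45, 0.50)


def occlusion_onset(p: TrajectoryParams, fraction: float) -> float:
    """Occlusion onset time: ``fraction`` of the return time.

    The fraction must fall in the short (20-25 %) or long (45-50 %)
    occlusion interval; the *last* part of the flight is hidden.
    """
    ok = (SHORT_OCCLUSION[0] <= fraction <= SHORT_OCCLUSION[1]
          or LONG_OCCLUSION[0] <= fraction <= LONG_OCCLUSION[1])
    if not ok:
        raise TrajectoryError(
            f"occlusion fraction {fraction} outside [0.20, 0.25] and [0.45, 0.50]")
    # the target disappears for the LAST `fraction` of the flight
    return (1.0 - fraction) * return_time(p)


def predict_ttc_1g(q: TtcQuery) -> float:
    """Drag-free earth-gravity time to the coincidence height.

    Solves ``d = (g_e/2) t^2 - v_up t`` (distance measured toward the
    coincidence height, ``v_up = v_y_last`` the away-from-coincidence
    velocity) and keeps the positive root

        t = (v_up + sqrt(v_up^2 + 2 g_e d)) / g_e.

    At ``d = 0`` this returns 0 unless the target is moving away, in
    which case it returns the earth-gravity up-and-back time.
    """
    v_up = q.v_y_last
    return (v_up + math.sqrt(v_up * v_up + 2.0 * q.g_earth * q.d_y)) / q.g_earth


def ttc_query_at(p: TrajectoryParams, t_occ: float, g_earth: float = G_EARTH) -> TtcQuery:
    """Extrapolation query from the true stimulus state at occlusion onset.

    The inverted geometry is mirrored into the toward-coincidence frame,
    so -1 g and +1 g stimuli with equal launch speeds yield identical
    queries.
    """
    st = position(p, t_occ)
    d_y = p.sign * (st.y - p.start_y)
    v_up = p.sign * st.vy  # away-from-coincidence positive
    return TtcQuery(v_y_last=v_up, d_y=max(d_y, 0.0), g_earth=g_earth)


def sample_trajectory(p: TrajectoryParams, rate_hz: float = 200.0,
                      t_occ: float | None = None) -> dict:
    """Sample the trajectory on a uniform grid up to the return time.

    Returns a dict of arrays (t, x, y, vx, vy, visible) suitable for
    delimited-text export; ``visible`` is 0 after occlusion onset.
    """
    T = return_time(p)
    t = np.arange(0.0, T + 0.5 / rate_hz, 1.0 / rate_hz)
    t = t[t <= T]
    st = position(p, t)
    visible = np.ones_like(t, dtype=int)
    if t_occ is not None:
        visible[t >= t_occ] = 0
    return {"t": t, "x": st.x, "y": st.y, "vx": st.vx, "vy": st.vy,
            "visible": visible}
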