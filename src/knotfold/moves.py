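"""Move set: crankshaft and pivot rotations, LTyP free-rotation intervals.

Both elementary moves rigidly rotate a contiguous set of beads about an
axis.  Crankshaft: the axis passes through the two beads flanking an
interior window.  Pivot: the axis passes through a single bead and the
beads between it and one terminus rotate; the axis direction is drawn
uniformly on the sphere.

In the linear-topology-preserving (LTyP) variant the rotation angle is
restricted to the free rotation interval — the maximal connected arc of
clash-free angles containing 0, obtained by intersecting, over every
(moving bead, fixed bead) pair, the arc within which the pair stays at or
beyond contact distance.  Because every bead pair is screened along the
whole rotation path, and because the bead radius (1.7 A) exceeds the
(3.9 A/2)(sqrt(2)/2) ~ 1.38 A bound below which two bonded sticks could
slip past each other between beads, LTyP moves can never take the chain
across itself.  The non-LTyP variant rotates by an unrestricted angle and
only screens the endpoint conformation for clashes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .model import Conformation, ModelParams


@dataclass
class MoveProposal:
    """One elementary move: kind, axis, moving window, and angle data."""

    kind: str                     # 'crankshaft' | 'pivot'
    axis_point: np.ndarray
    axis_dir: np.ndarray          # unit vector
    moving_start: int             # window [moving_start, moving_end)
    moving_end: int
    ltyp: bool = True
    angle: Optional[float] = None
    free_interval: Optional[Tuple[float, float]] = None

    @property
    def moving_size(self) -> int:
        return self.moving_end - self.moving_start


def max_moving_beads(n: int) -> int:
    """Largest permitted moving-set size: the largest integer < 3N/4."""
    return (3 * n - 1) // 4


def select_move(conf, rng: np.random.Generator,
                ltyp: bool = True) -> MoveProposal:
    """Draw move kind (p = 0.5 each), moving-set size and axis."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    if coords.shape[0] < 4:
        raise ValueError("move selection needs N >= 4")
    crank, mstart, mend, ax, ay, az, ux, uy, uz = _kernels.select_proposal(
        np.ascontiguousarray(coords, dtype=np.float64), rng)
    return MoveProposal(
        kind="crankshaft" if crank else "pivot",
        axis_point=np.array([ax, ay, az]),
        axis_dir=np.array([ux, uy, uz]),
        moving_start=int(mstart), moving_end=int(mend), ltyp=ltyp)


def free_rotation_interval(conf, proposal: MoveProposal,
                           params: ModelParams) -> Tuple[float, float]:
    """Free rotation interval (lo, hi) with lo <= 0 <= hi.

    Per (moving, fixed) pair the clockwise and counter-clockwise contact
    angles are solved in closed form on the rotation circle; the result is
    the intersection of all pairwise free arcs.  Grazing contact counts as
    free.  The current conformation must be clash-free, so 0 always lies in
    the interval.
    """
    coords = np.ascontiguousarray(
        conf.coords if isinstance(conf, Conformation) else conf,
        dtype=np.float64)
    a = proposal.axis_point
    u = proposal.axis_dir
    lo, hi = _kernels.free_rotation_interval(
        coords, proposal.moving_start, proposal.moving_end,
        a[0], a[1], a[2], u[0], u[1], u[2], params.bead_radius)
    assert lo <= 0.0 <= hi, "free interval must contain the identity angle"
    proposal.free_interval = (float(lo), float(hi))
    return proposal.free_interval


def propose_angle(proposal: MoveProposal, rng: np.random.Generator) -> float:
    """Draw the rotation angle: uniform on the free interval (LTyP) or on
    (-pi, pi] (non-LTyP)."""
    if proposal.ltyp:
        if proposal.free_interval is None:
            raise ValueError("LTyP proposal lacks a computed free_interval")
        lo, hi = proposal.free_interval
        angle = lo + rng.random() * (hi - lo)
    else:
        angle = -np.pi + rng.random() * 2.0 * np.pi
    proposal.angle = float(angle)
    return proposal.angle


def apply_and_screen(conf, proposal: MoveProposal, params: ModelParams,
                     check_ltyp: bool = False) -> Optional[Conformation]:
    """Rotate the moving window; screen the trial conformation.

    Returns the trial Conformation, or None when a non-LTyP trial has a
    steric clash (rejected before the Metropolis test).  With check_ltyp,
    asserts that an LTyP trial is clash-free (it must be, by construction).
    """
    if proposal.angle is None:
        raise ValueError("proposal has no angle set")
    coords = np.array(conf.coords if isinstance(conf, Conformation) else conf,
                      dtype=np.float64)
    a = proposal.axis_point
    u = proposal.axis_dir
    _kernels.rotate_range(coords, proposal.moving_start, proposal.moving_end,
                          a[0], a[1], a[2], u[0], u[1], u[2], proposal.angle)
    clash = _kernels.has_clash_moving(coords, proposal.moving_start,
                                      proposal.moving_end, params.bead_radius)
    if proposal.ltyp:
        if check_ltyp:
            assert not clash, "LTyP trial conformation has a steric clash"
    elif clash:
        return None
    return Conformation(coords)


def min_nonadjacent_stick_distance(coords: np.ndarray) -> float:
    """Minimum distance between non-adjacent backbone sticks (debug helper).

    A chain crossing would drive one of these distances through zero; the
    helper lets tests scan a rotation path densely and verify that LTyP
    moves never thread one bonded pair through another.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    best = np.inf
    for i in range(n - 1):
        for j in range(i + 2, n - 1):
            best = min(best, _segment_distance(coords[i], coords[i + 1],
                                               coords[j], coords[j + 1]))
    return best


def _segment_distance(p1, p2, q1, q2) -> float:
    """Euclidean distance between two 3D segments."""
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    c = d1 @ r
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-14 else 0.0
    t = (b * s + f) / e if e > 1e-14 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-14 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-14 else 0.0
    return float(np.linalg.norm(p1 + d1 * s - (q1 + d2 * t)))


def min_crossing_safe_radius(max_bond: float = 3.9) -> float:
    """Smallest bead radius at which bead overlap forbids stick crossing.

    Two bonded sticks of length ``max_bond`` can only pass through each
    other if, at the instant their segments intersect, no two of the four
    beads overlap.  The worst case maximises, over all intersecting
    segment-pair geometries, the smallest bead-bead distance; half that
    distance is the minimal safe radius.  Solved numerically by maximising
    over the intersection-point offsets along both sticks and the relative
    stick orientation (the optimum is two perpendicular sticks crossing at
    their midpoints, giving max_bond * sqrt(2)/4).
    """
    b = max_bond

    def neg_min_gap(x):
        s, t, theta, phi = x
        u = np.array([np.cos(theta) * np.cos(phi),
                      np.cos(theta) * np.sin(phi),
                      np.sin(theta)])
        ends1 = np.array([[-s, 0.0, 0.0], [b - s, 0.0, 0.0]])
        ends2 = np.array([-t * u, (b - t) * u])
        d = np.linalg.norm(ends1[:, None, :] - ends2[None, :, :], axis=-1)
        return -d.min()

    best = 0.0
    for s0 in (0.25 * b, 0.5 * b, 0.75 * b):
        for th0 in (0.3, np.pi / 2, 2.5):
            res = minimize(neg_min_gap, x0=[s0, s0, th0, th0],
                           method="Nelder-Mead",
                           bounds=[(0, b), (0, b), (0, np.pi), (0, np.pi)],
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 5000})
            best = max(best, -res.fun)
    return best / 2.0
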