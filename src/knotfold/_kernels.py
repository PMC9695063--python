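"""Numba-compiled geometry and Monte Carlo kernels.

All kernels operate on plain float64 arrays.  The same jitted routines back
both the user-facing API (one call per operation) and the sampler hot loop
(`mc_block`), so there is a single implementation of each geometric
primitive.

Conventions: coordinates in angstrom, energies and temperatures in reduced
units (kB = 1), bead indices 0-based.  Contact lists are stored as parallel
arrays (ci, cj, d_nat, chirality data) with ci < cj.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def chirality(coords, i, j):
    """Signed half-unit chirality of ordered contact (i, j).

    Theta((r_i - r_j) . [(r_{j+1} - r_j) x (r_{j-1} - r_j)]) - 1/2 with
    Theta(x) = 1 iff x > 0.  Caller must ensure 0 < j < N-1.
    """
    ax = coords[i, 0] - coords[j, 0]
    ay = coords[i, 1] - coords[j, 1]
    az = coords[i, 2] - coords[j, 2]
    bx = coords[j + 1, 0] - coords[j, 0]
    by = coords[j + 1, 1] - coords[j, 1]
    bz = coords[j + 1, 2] - coords[j, 2]
    cx = coords[j - 1, 0] - coords[j, 0]
    cy = coords[j - 1, 1] - coords[j, 1]
    cz = coords[j - 1, 2] - coords[j, 2]
    # b x c
    px = by * cz - bz * cy
    py = bz * cx - bx * cz
    pz = bx * cy - by * cx
    triple = ax * px + ay * py + az * pz
    if triple > 0.0:
        return 0.5
    return -0.5


@njit(cache=True)
def total_energy(coords, ci, cj, d_nat, chin_ij, def_ij, chin_ji, def_ji,
                 eps, w):
    """Full Go energy: eps * sum over native contacts of well * chirality factor.

    The chirality factor is (chi_ij chi_ij_nat + chi_ji chi_ji_nat + 1/2);
    a product whose chirality is undefined (terminal bead) contributes its
    native-matching value +1/4.
    """
    n = coords.shape[0]
    e = 0.0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        u = (d - d_nat[k]) / w
        phi = 1.0 / (u * u + 1.0)
        if def_ij[k]:
            a = chirality(coords, i, j) * chin_ij[k]
        else:
            a = 0.25
        if def_ji[k]:
            b = chirality(coords, j, i) * chin_ji[k]
        else:
            b = 0.25
        e += eps * phi * (a + b + 0.5)
    return e


@njit(cache=True)
def native_contact_count(coords, ci, cj, d_nat, w):
    """Number of native contacts currently formed (|d - d_nat| < w, strict)."""
    c = 0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if abs(d - d_nat[k]) < w:
            c += 1
    return c


@njit(cache=True)
def rotate_range(coords, mstart, mend, ax, ay, az, ux, uy, uz, angle):
    """Rodrigues rotation of beads [mstart, mend) about axis point a, unit u."""
    c = math.cos(angle)
    s = math.sin(angle)
    for p in range(mstart, mend):
        vx = coords[p, 0] - ax
        vy = coords[p, 1] - ay
        vz = coords[p, 2] - az
        dot = vx * ux + vy * uy + vz * uz
        # u x v
        wx = uy * vz - uz * vy
        wy = uz * vx - ux * vz
        wz = ux * vy - uy * vx
        coords[p, 0] = ax + vx * c + wx * s + ux * dot * (1.0 - c)
        coords[p, 1] = ay + vy * c + wy * s + uy * dot * (1.0 - c)
        coords[p, 2] = az + vz * c + wz * s + uz * dot * (1.0 - c)


@njit(cache=True)
def has_clash_moving(coords, mstart, mend, radius):
    """True if any (moving, fixed) pair with |i-j| >= 2 is closer than 2*radius.

    Only moving-vs-fixed pairs can change during a rigid rotation of the
    window, so other pairs are not rechecked.
    """
    n = coords.shape[0]
    c2 = 4.0 * radius * radius
    for p in range(mstart, mend):
        for f in range(n):
            if mstart <= f < mend:
                continue
            sep = p - f
            if -2 < sep < 2:
                continue
            dx = coords[p, 0] - coords[f, 0]
            dy = coords[p, 1] - coords[f, 1]
            dz = coords[p, 2] - coords[f, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                return True
    return False


@njit(cache=True)
def has_clash_full(coords, radius):
    """True if any non-bonded pair (sequence separation >= 2) overlaps."""
    n = coords.shape[0]
    c2 = 4.0 * radius * radius
    for i in range(n):
        for j in range(i + 2, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                return True
    return False


@njit(cache=True)
def free_rotation_interval(coords, mstart, mend, ax, ay, az, ux, uy, uz,
                           radius):
    """Maximal connected clash-free rotation arc containing angle 0.

    For each (moving, fixed) pair that can reach contact distance
    c = 2*radius under the rotation, the contact angles are solved in closed
    form (law of cosines on the rotation circle) and the per-pair free arcs
    are intersected.  Grazing contact (distance exactly c) is allowed.

    Returns (lo, hi) with lo <= 0 <= hi.  The bounds are true contact
    angles on the circle and may extend beyond +-pi (never spanning more
    than 2*pi in total); capping them at +-pi would shorten the arc by a
    state-dependent amount and break the symmetry of the LTyP proposal.
    The unrestricted case returns (-pi, pi).
    """
    n = coords.shape[0]
    c = 2.0 * radius
    c2 = c * c
    lo = -TWO_PI
    hi = TWO_PI
    for p in range(mstart, mend):
        vx = coords[p, 0] - ax
        vy = coords[p, 1] - ay
        vz = coords[p, 2] - az
        hp = vx * ux + vy * uy + vz * uz
        rx = vx - hp * ux
        ry = vy - hp * uy
        rz = vz - hp * uz
        rr = math.sqrt(rx * rx + ry * ry + rz * rz)
        if rr < 1e-12:
            continue  # bead on the axis: it does not move
        e1x = rx / rr
        e1y = ry / rr
        e1z = rz / rr
        # e2 = u x e1 completes the right-handed in-plane frame
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
        for f in range(n):
            if mstart <= f < mend:
                continue
            sep = p - f
            if -2 < sep < 2:
                continue  # bonded neighbours are exempt from excluded volume
            gx = coords[f, 0] - ax
            gy = coords[f, 1] - ay
            gz = coords[f, 2] - az
            hf = gx * ux + gy * uy + gz * uz
            sx = gx - hf * ux
            sy = gy - hf * uy
            sz = gz - hf * uz
            dd = math.sqrt(sx * sx + sy * sy + sz * sz)
            dh = hp - hf
            # cheapest reject: the closest approach over all angles
            gap = rr - dd
            if dh * dh + gap * gap >= c2:
                continue
            if dd < 1e-12:
                continue  # fixed bead on the axis: distance is constant
            cosb = (rr * rr + dd * dd + dh * dh - c2) / (2.0 * rr * dd)
            if cosb >= 1.0:
                continue  # never reaches contact
            if cosb < -1.0:
                cosb = -1.0  # numerical guard; cannot occur clash-free
            beta = math.acos(cosb)
            # azimuth of the fixed bead in the moving bead's rotation frame
            psi = math.atan2(sx * e2x + sy * e2y + sz * e2z,
                             sx * e1x + sy * e1y + sz * e1z)
            # blocked arc: alpha in (psi - beta, psi + beta) mod 2*pi
            ccw = psi - beta
            while ccw < 0.0:
                ccw += TWO_PI
            while ccw >= TWO_PI:
                ccw -= TWO_PI
            cw = psi + beta
            while cw > 0.0:
                cw -= TWO_PI
            while cw <= -TWO_PI:
                cw += TWO_PI
            if ccw < hi:
                hi = ccw
            if cw > lo:
                lo = cw
    if hi == TWO_PI:
        # no pair restricts the rotation: every angle is free
        return -math.pi, math.pi
    return lo, hi


@njit(cache=True)
def max_bond_deviation(coords, bond_lengths):
    dev = 0.0
    for i in range(coords.shape[0] - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        e = abs(d - bond_lengths[i])
        if e > dev:
            dev = e
    return dev


@njit(cache=True)
def _random_unit(rng):
    # Marsaglia rejection on the unit sphere
    while True:
        x = 2.0 * rng.random() - 1.0
        y = 2.0 * rng.random() - 1.0
        z = 2.0 * rng.random() - 1.0
        s = x * x + y * y + z * z
        if 1e-12 < s <= 1.0:
            r = 1.0 / math.sqrt(s)
            return x * r, y * r, z * r


@njit(cache=True)
def select_proposal(coords, rng):
    """Draw one elementary move: kind, moving window, rotation axis.

    Kind is crankshaft or pivot with p = 0.5 each; the moving-set size m is
    uniform on {1, ..., m_max} with m_max the largest integer strictly
    below 3N/4; infeasible (kind, m) draws are redrawn.  Returns
    (is_crankshaft, mstart, mend, ax, ay, az, ux, uy, uz) with the moving
    beads occupying [mstart, mend) and a unit axis direction u through the
    axis point a.
    """
    n = coords.shape[0]
    m_max = (3 * n - 1) // 4
    while True:
        crank = rng.random() < 0.5
        m = 1 + int(rng.random() * m_max)
        if m > m_max:
            m = m_max
        if crank:
            if m <= n - 2:
                break
        else:
            break  # pivot feasible for all m <= m_max <= N-1 (N >= 4)
    if crank:
        # interior window [s, s+m), axis through flanking beads s-1 and s+m
        s = 1 + int(rng.random() * (n - 1 - m))
        if s > n - 1 - m:
            s = n - 1 - m
        mstart = s
        mend = s + m
        ax = coords[s - 1, 0]
        ay = coords[s - 1, 1]
        az = coords[s - 1, 2]
        ux = coords[s + m, 0] - ax
        uy = coords[s + m, 1] - ay
        uz = coords[s + m, 2] - az
        un = math.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= un
        uy /= un
        uz /= un
    else:
        # pivot: random terminus, axis bead at distance m, random direction
        if rng.random() < 0.5:
            mstart = 0
            mend = m
            pivot = m
        else:
            mstart = n - m
            mend = n
            pivot = n - m - 1
        ax = coords[pivot, 0]
        ay = coords[pivot, 1]
        az = coords[pivot, 2]
        ux, uy, uz = _random_unit(rng)
    return crank, mstart, mend, ax, ay, az, ux, uy, uz


@njit(cache=True)
def mc_block(coords, energy, temp, n_steps, ci, cj, d_nat,
             chin_ij, def_ij, chin_ji, def_ji, eps, w, radius,
             ltyp, rng, check_ltyp):
    """Advance one replica by n_steps Metropolis Monte Carlo steps.

    One step = one elementary move proposal (crankshaft or pivot, p = 0.5
    each).  LTyP proposals draw the angle uniformly on the free rotation
    interval; non-LTyP proposals draw uniformly on (-pi, pi] and reject
    trial conformations with steric clashes before the Metropolis test.

    Mutates `coords` in place; returns (energy, n_accepted).  With
    check_ltyp, asserts that LTyP trials are clash-free (returns -1 accepted
    count as an error signal instead of raising, numba-friendly).
    """
    trial = np.empty_like(coords)
    n_acc = 0
    for _ in range(n_steps):
        crank, mstart, mend, ax, ay, az, ux, uy, uz = \
            select_proposal(coords, rng)

        if ltyp:
            lo, hi = free_rotation_interval(coords, mstart, mend,
                                            ax, ay, az, ux, uy, uz, radius)
            angle = lo + rng.random() * (hi - lo)
        else:
            angle = -math.pi + rng.random() * TWO_PI

        trial[:] = coords
        rotate_range(trial, mstart, mend, ax, ay, az, ux, uy, uz, angle)

        if ltyp:
            if check_ltyp and has_clash_moving(trial, mstart, mend, radius):
                return energy, -1
        else:
            if has_clash_moving(trial, mstart, mend, radius):
                continue  # rejected; still counts as one mcs

        e_new = total_energy(trial, ci, cj, d_nat, chin_ij, def_ij,
                             chin_ji, def_ji, eps, w)
        de = e_new - energy
        if de <= 0.0 or rng.random() < math.exp(-de / temp):
            coords[:] = trial
            energy = e_new
            n_acc += 1
    return energy, n_acc
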