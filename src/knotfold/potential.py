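"""Chirality-augmented Go potential and the folding reaction coordinate Q.

Energy of a conformation {r_i}:

    E = eps * sum_{native contacts (i,j), j >= i+2}
            phi(|d_ij - d_ij^nat|) * (chi_ij chi_ij^nat
                                      + chi_ji chi_ji^nat + 1/2)

with the inverse-quadratic well phi(x) = [ (x/w)^2 + 1 ]^(-1) and signed
half-unit chiralities chi built from the scalar triple product of the
contact vector with the two backbone bonds flanking the pivot bead.  The
chirality factor is 1 when both contact chiralities match the native ones,
0 for the mirror geometry, and 1/2 when exactly one matches, so the native
state is the global energy minimum at E = eps * Nc while its mirror image
gains nothing from the contact wells.

A native contact counts as *formed* when its bead distance differs from the
native distance by less than the well half-width w (strict); Q is the
formed fraction.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .model import (ChiralityUndefinedError, Conformation, ModelParams,
                    NativeTopology, TopologyError)


def _coords_of(conf) -> np.ndarray:
    if isinstance(conf, Conformation):
        return conf.coords
    return np.ascontiguousarray(conf, dtype=np.float64)


def contact_chirality(conf, i: int, j: int) -> float:
    """Signed half-unit chirality chi_ij of the ordered contact (i, j).

    Theta((r_i - r_j) . [(r_{j+1} - r_j) x (r_{j-1} - r_j)]) - 1/2, where
    Theta(0) = 0, so a coplanar geometry maps to -1/2.  Requires both
    sequence neighbours of j.
    """
    coords = _coords_of(conf)
    n = coords.shape[0]
    if i == j:
        raise ValueError("i and j must differ")
    if not (0 < j < n - 1):
        raise ChiralityUndefinedError(
            f"chirality of ({i},{j}) undefined: bead {j} is terminal")
    return float(_kernels.chirality(coords, i, j))


def pair_energy_term(d: float, d_nat: float, w: float) -> float:
    """Inverse-quadratic well value [((d - d_nat)/w)^2 + 1]^(-1) in (0, 1]."""
    if not w > 0:
        raise ValueError("w must be positive")
    u = (np.asarray(d) - d_nat) / w
    return 1.0 / (u * u + 1.0)


def _check_dims(coords, topo: NativeTopology):
    if coords.shape[0] != topo.n_beads:
        raise TopologyError(
            f"conformation has {coords.shape[0]} beads, topology "
            f"{topo.n_beads}")


def total_energy(conf, topo: NativeTopology, params: ModelParams) -> float:
    """Total reduced energy of a conformation under the native topology."""
    coords = _coords_of(conf)
    _check_dims(coords, topo)
    return float(_kernels.total_energy(
        coords, topo.ci, topo.cj, topo.native_distances,
        topo.chin_ij, topo.def_ij, topo.chin_ji, topo.def_ji,
        params.epsilon, params.w))


def fraction_native(conf, topo: NativeTopology, params: ModelParams) -> float:
    """Fraction Q of native contacts formed (|d - d_nat| < w, strict)."""
    coords = _coords_of(conf)
    _check_dims(coords, topo)
    if topo.n_contacts == 0:
        raise TopologyError("topology has no native contacts; Q undefined")
    formed = _kernels.native_contact_count(
        coords, topo.ci, topo.cj, topo.native_distances, params.w)
    return formed / topo.n_contacts


def chirality_factor(conf, topo: NativeTopology, k: int) -> float:
    """Chirality factor of contact index k in {0, 1/2, 1}.

    Each ordered product chi * chi^nat contributes +1/4 (match) or -1/4
    (mirror); an order whose chirality is undefined (terminal pivot bead)
    contributes the native-matching +1/4.
    """
    coords = _coords_of(conf)
    i, j = int(topo.ci[k]), int(topo.cj[k])
    a = (_kernels.chirality(coords, i, j) * topo.chin_ij[k]
         if topo.def_ij[k] else 0.25)
    b = (_kernels.chirality(coords, j, i) * topo.chin_ji[k]
         if topo.def_ji[k] else 0.25)
    return a + b + 0.5


def evaluate(conf, topo: NativeTopology, params: ModelParams) -> Conformation:
    """Return a Conformation with freshly cached energy and Q."""
    coords = _coords_of(conf)
    out = Conformation(coords.copy())
    out.energy = total_energy(out, topo, params)
    out.q = fraction_native(out, topo, params)
    return out


def is_clash_free(conf, params: ModelParams) -> bool:
    """True if no non-bonded pair (separation >= 2) overlaps (< 2*radius)."""
    return not _kernels.has_clash_full(_coords_of(conf), params.bead_radius)
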