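"""Synthetic native topologies and starting states.

These generators make the whole pipeline testable without any structure
downloads: deterministic toy folds (hairpin, helix, compact globule), an
open-trefoil knotted chain, and hot-run denatured starting conformations.

Synthetic topologies have no side chains, so their contact maps use a
C-alpha distance proxy (contact iff native C-alpha distance <= 6.5 A,
sequence separation >= 2) instead of the 4.5 A heavy-atom rule used for
real structures; the rule in force is recorded in ``topology.metadata``.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .model import Conformation, ModelParams, NativeTopology, TopologyError

CA_PROXY_CUTOFF = 6.5   # angstrom, C-alpha proxy for the heavy-atom rule
BOND = 3.8              # trans C-alpha--C-alpha bond length, angstrom
MIN_CLEARANCE = 3.4     # 2 x 1.7 A bead radius


def _proxy_contacts(coords, cutoff=CA_PROXY_CUTOFF):
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    iu = np.triu_indices(n, 2)
    mask = d[iu] <= cutoff
    return list(zip(iu[0][mask], iu[1][mask]))


def _finish_topology(coords, metadata, cutoff=CA_PROXY_CUTOFF):
    coords = np.asarray(coords, dtype=np.float64)
    if _kernels.has_clash_full(coords, MIN_CLEARANCE / 2.0):
        raise TopologyError("synthetic native geometry has steric clashes")
    topo = NativeTopology.from_coords(coords, _proxy_contacts(coords, cutoff),
                                      metadata=metadata)
    topo.validate()
    return topo


def _hairpin_coords(n):
    """Two antiparallel strands 5.2 A apart joined by a tight turn.

    A small alternating out-of-plane pucker keeps every contact's triple
    product away from zero: in an exactly planar chain the chirality term
    sits on its Theta(0) discontinuity and numerical noise after rigid
    motions could flip it.
    """
    sep = 5.2
    if n % 2 == 1:
        m = (n - 1) // 2
        turn = 1
    else:
        m = (n - 2) // 2
        turn = 2
    length = BOND * (m - 1)
    pts = [(BOND * i, 0.0, 0.0) for i in range(m)]
    if turn == 1:
        h = np.sqrt(BOND ** 2 - (sep / 2) ** 2)
        pts.append((length + h, sep / 2, 0.0))
    else:
        half_gap = (sep - BOND) / 2
        h = np.sqrt(BOND ** 2 - half_gap ** 2)
        pts.append((length + h, half_gap, 0.0))
        pts.append((length + h, sep - half_gap, 0.0))
    pts.extend((length - BOND * i, sep, 0.0) for i in range(m))
    out = np.array(pts)
    out[:, 2] = 0.3 * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    return out


def _helix_coords(n):
    """Ideal alpha-helical C-alpha trace (r = 2.3 A, rise 1.5 A, 100 deg)."""
    i = np.arange(n)
    phi = np.deg2rad(100.0) * i
    return np.stack([2.3 * np.cos(phi), 2.3 * np.sin(phi), 1.5 * i], axis=1)


def _globule_coords(n, rng):
    """Self-avoiding fixed-bond random walk biased toward its centroid."""
    for _ in range(200):  # restart until a full chain grows
        pts = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            centroid = np.mean(pts, axis=0)
            for _try in range(200):
                step = rng.normal(size=3)
                pull = centroid - pts[-1]
                norm = np.linalg.norm(pull)
                if norm > 1e-9:
                    step = step + 0.7 * pull / norm * np.linalg.norm(step)
                step *= BOND / np.linalg.norm(step)
                cand = pts[-1] + step
                d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1) \
                    if len(pts) > 1 else np.array([np.inf])
                if (d >= MIN_CLEARANCE + 0.05).all():
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise TopologyError("failed to grow a clash-free compact globule")


def make_toy_topology(kind: str, n: int, seed: int = 0) -> NativeTopology:
    """Deterministic toy native topology: hairpin, helix or compact_globule.

    All variants use 3.8 A bonds and the 6.5 A C-alpha contact proxy.
    """
    if n < 8:
        raise ValueError("toy topologies need n >= 8")
    if kind == "hairpin":
        coords = _hairpin_coords(n)
    elif kind == "helix":
        coords = _helix_coords(n)
    elif kind == "compact_globule":
        coords = _globule_coords(n, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown toy kind {kind!r}")
    return _finish_topology(coords, {"contact_rule": "ca_proxy_6.5",
                                     "kind": kind, "seed": seed})


def trefoil_curve(n: int, t_margin: float = 0.1,
                  t_cut: float = np.pi) -> np.ndarray:
    """Open trefoil arc resampled to n points at equal chord length.

    Parametric family (sin t + 2 sin 2t, cos t - 2 cos 2t, -sin 3t) on
    t in [t_cut + t_margin, t_cut + 2*pi - t_margin]; chords are equalised
    iteratively and then pinned to exactly 3.8 A.  The default cut point
    t_cut = pi opens the curve at a lobe tip (its outermost point), so both
    termini sit on the chain surface as they do in knotted proteins; a cut
    near t = 0 would bury the termini in the centre of the knot.
    """
    t = np.linspace(t_cut + t_margin, t_cut + 2 * np.pi - t_margin, 20000)
    pts = np.stack([np.sin(t) + 2 * np.sin(2 * t),
                    np.cos(t) - 2 * np.cos(2 * t),
                    -np.sin(3 * t)], axis=1)
    for _ in range(20):
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        si = np.linspace(0.0, s[-1], n)
        pts = np.stack([np.interp(si, s, pts[:, k]) for k in range(3)],
                       axis=1)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    pts *= BOND / seg.mean()
    # pin every chord to exactly BOND (negligible shape change)
    out = np.empty_like(pts)
    out[0] = pts[0]
    for i in range(n - 1):
        v = pts[i + 1] - pts[i]
        out[i + 1] = out[i] + v * (BOND / np.linalg.norm(v))
    return out


KNOTTED_PROXY_CUTOFF = 8.5


def make_knotted_topology(n: int = 35) -> NativeTopology:
    """Open-trefoil native topology: a desk-scale knotted model system.

    The native state embeds a 3_1 knot.  Its contact proxy cutoff is 8.5 A
    (denser than the 6.5 A used for the unknotted toys): with a sparse map
    an unknotted conformation can satisfy essentially every native contact
    well, so nothing in the potential enforces threading and the
    low-temperature ensemble would not be knotted.  At 8.5 A (76 contacts
    at n = 35) annealed unknotted chains plateau about eleven contact
    energies above the knotted thermal band, so the knotted basin dominates
    at low temperature as it must for a knotted protein model.
    """
    if n < 30:
        raise ValueError("knotted fixture needs n >= 30")
    coords = trefoil_curve(n)
    topo = _finish_topology(coords, {"contact_rule": "ca_proxy_8.5",
                                     "kind": "trefoil"},
                            cutoff=KNOTTED_PROXY_CUTOFF)
    from .knots import is_knotted, knot_type_of_open_chain
    if knot_type_of_open_chain(coords) != "3_1" or not is_knotted(coords):
        raise TopologyError("trefoil fixture failed its own knot check")
    return topo


def extended_conformation(topo: NativeTopology) -> Conformation:
    """Fully extended straight chain with the topology's bond lengths."""
    n = topo.n_beads
    coords = np.zeros((n, 3))
    coords[1:, 0] = np.cumsum(topo.bond_lengths)
    return Conformation(coords)


def generate_denatured(topo: NativeTopology, params: ModelParams,
                       t_hot: float, budget_mcs: int,
                       seed: int = 0) -> Conformation:
    """Denatured, unknotted starting conformation from a hot MC run.

    Runs single-temperature non-LTyP Metropolis MC at t_hot starting from
    the extended chain; re-runs with a fresh sub-seed until the final
    conformation is unknotted and has Q < 0.2 (at most 10 attempts).
    """
    from .knots import is_knotted
    from .potential import fraction_native

    for attempt in range(10):
        rng = np.random.default_rng([seed, attempt])
        conf = extended_conformation(topo)
        coords = conf.coords
        energy = float(_kernels.total_energy(
            coords, topo.ci, topo.cj, topo.native_distances,
            topo.chin_ij, topo.def_ij, topo.chin_ji, topo.def_ji,
            params.epsilon, params.w))
        energy, _ = _kernels.mc_block(
            coords, energy, t_hot, int(budget_mcs),
            topo.ci, topo.cj, topo.native_distances,
            topo.chin_ij, topo.def_ij, topo.chin_ji, topo.def_ji,
            params.epsilon, params.w, params.bead_radius,
            False, rng, False)
        out = Conformation(coords, energy)
        out.q = fraction_native(out, topo, params)
        if out.q < 0.2 and not is_knotted(coords):
            return out
    raise RuntimeError(
        "could not generate an unknotted denatured conformation in 10 "
        "attempts; raise t_hot or budget_mcs")
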