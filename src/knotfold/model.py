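"""Core data containers: model parameters, native topology, conformation.

The simulator represents a protein as a chain of hard spherical beads
centred on the C-alpha positions, joined by rigid sticks whose lengths are
the native C-alpha--C-alpha distances.  Only native contacts interact
(structure-based / Go potential); each contact carries its native distance
and native chirality signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels


class TopologyError(ValueError):
    """Raised for inconsistent or degenerate native topologies."""


class ChiralityUndefinedError(ValueError):
    """Chirality of an ordered contact (i, j) is undefined at a terminal j."""


@dataclass(frozen=True)
class ModelParams:
    """Interaction parameters of the chirality-augmented Go potential.

    Parameters
    ----------
    epsilon : float
        Uniform intramolecular energy per native contact, reduced units.
        Must be negative (attractive); the default -1 sets the energy scale.
    w : float
        Half-width of the inverse-quadratic contact well, in angstrom.
        Controls folding cooperativity: wider wells melt at higher
        temperature with broader heat-capacity peaks.
    bead_radius : float
        Hard-sphere bead radius in angstrom.  The default 1.7 (C-alpha van
        der Waals radius) exceeds the 1.38 A bound below which bead-bead
        exclusion alone no longer forbids chain crossing at 3.9 A bonds.
    contact_cutoff : float
        Heavy-atom distance cutoff defining native contacts, angstrom.
    """

    epsilon: float = -1.0
    w: float = 1.0
    bead_radius: float = 1.7
    contact_cutoff: float = 4.5

    def __post_init__(self):
        if not self.epsilon < 0:
            raise ValueError("epsilon must be negative (attractive contacts)")
        if not self.w > 0:
            raise ValueError("well half-width w must be positive")
        if not self.bead_radius > 0:
            raise ValueError("bead_radius must be positive")
        if not self.contact_cutoff > 0:
            raise ValueError("contact_cutoff must be positive")


def native_chirality_arrays(coords: np.ndarray, ci: np.ndarray,
                            cj: np.ndarray):
    """Native chirality signs for both orders of every contact.

    Returns (chin_ij, def_ij, chin_ji, def_ji): the signed half-unit
    chirality of (i, j) -- which needs both sequence neighbours of j -- and
    a definedness flag that is false when the pivot bead is a terminus.
    """
    n = coords.shape[0]
    m = ci.shape[0]
    chin_ij = np.zeros(m)
    chin_ji = np.zeros(m)
    def_ij = np.zeros(m, dtype=np.uint8)
    def_ji = np.zeros(m, dtype=np.uint8)
    for k in range(m):
        i, j = int(ci[k]), int(cj[k])
        if 0 < j < n - 1:
            chin_ij[k] = _kernels.chirality(coords, i, j)
            def_ij[k] = 1
        if 0 < i < n - 1:
            chin_ji[k] = _kernels.chirality(coords, j, i)
            def_ji[k] = 1
    return chin_ij, def_ij, chin_ji, def_ji


@dataclass
class NativeTopology:
    """Native reference state of a chain: geometry, contacts, chirality.

    Contacts are stored as parallel arrays with ci < cj and sequence
    separation >= 2.  ``residue_numbers`` maps 0-based bead indices to the
    source-structure residue numbering used in reports.
    """

    native_coords: np.ndarray           # (N, 3) angstrom
    ci: np.ndarray                      # contact partner i (int)
    cj: np.ndarray                      # contact partner j (int), cj > ci
    native_distances: np.ndarray        # C-alpha distance per contact
    bond_lengths: np.ndarray            # (N-1,) consecutive C-alpha distances
    chin_ij: np.ndarray
    def_ij: np.ndarray
    chin_ji: np.ndarray
    def_ji: np.ndarray
    residue_numbers: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return self.native_coords.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.ci.shape[0]

    @property
    def contact_map(self) -> np.ndarray:
        """Symmetric boolean native contact map (Delta^nat)."""
        n = self.n_beads
        cmap = np.zeros((n, n), dtype=bool)
        cmap[self.ci, self.cj] = True
        cmap[self.cj, self.ci] = True
        return cmap

    @classmethod
    def from_coords(cls, native_coords, contact_pairs, residue_numbers=None,
                    metadata=None) -> "NativeTopology":
        """Build a topology from native C-alpha coordinates and contact pairs.

        ``contact_pairs`` is an iterable of (i, j) bead-index pairs; order
        within a pair is ignored, duplicates are collapsed, and pairs with
        sequence separation < 2 are rejected.
        """
        coords = np.ascontiguousarray(native_coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
            raise TopologyError("native_coords must be (N>=4, 3)")
        n = coords.shape[0]
        pairs = set()
        for i, j in contact_pairs:
            i, j = int(i), int(j)
            if i > j:
                i, j = j, i
            if j - i < 2:
                raise TopologyError(
                    f"contact ({i},{j}) has sequence separation < 2")
            if not (0 <= i and j < n):
                raise TopologyError(f"contact ({i},{j}) out of range")
            pairs.add((i, j))
        pairs = sorted(pairs)
        ci = np.array([p[0] for p in pairs], dtype=np.int64)
        cj = np.array([p[1] for p in pairs], dtype=np.int64)
        d_nat = np.linalg.norm(coords[ci] - coords[cj], axis=1) \
            if len(pairs) else np.zeros(0)
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        chin_ij, def_ij, chin_ji, def_ji = native_chirality_arrays(
            coords, ci, cj)
        if residue_numbers is None:
            residue_numbers = np.arange(1, n + 1)
        return cls(coords, ci, cj, d_nat, bonds, chin_ij, def_ij,
                   chin_ji, def_ji, np.asarray(residue_numbers),
                   dict(metadata or {}))

    def validate(self, params: Optional[ModelParams] = None):
        """Check internal consistency; raise TopologyError on violation."""
        coords = self.native_coords
        d = np.linalg.norm(coords[self.ci] - coords[self.cj], axis=1)
        if self.n_contacts and not np.allclose(d, self.native_distances,
                                               atol=1e-9):
            raise TopologyError("native_distances inconsistent with coords")
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if not np.allclose(bonds, self.bond_lengths, atol=1e-9):
            raise TopologyError("bond_lengths inconsistent with coords")
        if np.any(self.cj - self.ci < 2):
            raise TopologyError("contact with sequence separation < 2")
        if params is not None and _kernels.has_clash_full(
                coords, params.bead_radius):
            raise TopologyError("native conformation has steric clashes")


@dataclass
class Conformation:
    """Current chain state: bead coordinates plus cached E and Q."""

    coords: np.ndarray
    energy: float = None
    q: float = None

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), self.energy, self.q)


def enforce_bonds(coords: np.ndarray, bond_lengths: np.ndarray) -> np.ndarray:
    """Rescale each bond vector to its exact native length (drift repair)."""
    out = np.empty_like(coords)
    out[0] = coords[0]
    for i in range(coords.shape[0] - 1):
        v = coords[i + 1] - coords[i]
        v *= bond_lengths[i] / np.linalg.norm(v)
        out[i + 1] = out[i] + v
    return out
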