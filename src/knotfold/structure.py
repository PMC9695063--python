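"""Build native topologies from all-atom structures; tail engineering; I/O.

A native contact joins two residues with sequence separation >= 2 whose
closest heavy atoms lie within the contact cutoff (4.5 A, inclusive) in the
native structure; bead geometry comes from the C-alpha trace.  Synthetic
C-alpha-only inputs fall back to a C-alpha distance proxy recorded in the
topology metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .model import ModelParams, NativeTopology, TopologyError

HEAVY_ATOM_RULE = "heavy_atom_4.5"
_BOND_WARN = (2.7, 4.1)
_BOND_HARD = (1.0, 6.0)


@dataclass
class ResidueAtoms:
    """Heavy-atom coordinates of one residue plus its C-alpha."""

    res_id: int
    name: str
    ca: np.ndarray             # (3,)
    heavy: np.ndarray          # (k, 3), includes the C-alpha


def load_structure(path, chain_id: Optional[str] = None,
                   model_index: int = 0) -> List[ResidueAtoms]:
    """Read a PDB/mmCIF file into per-residue heavy-atom coordinate sets.

    Keeps the highest-occupancy alternate locations, drops hydrogens and
    hetero records, and returns residues in chain order.  Raises on a
    missing chain or on residues without a C-alpha.
    """
    import biotite.structure as struc
    from biotite.structure.io import load_structure as _bt_load

    arr = _bt_load(str(path), model=model_index + 1, altloc="occupancy")
    arr = arr[struc.filter_amino_acids(arr)]
    if arr.array_length() == 0:
        raise TopologyError(f"{path}: no protein residues found")
    chains = list(dict.fromkeys(arr.chain_id))
    if chain_id is None:
        chain_id = chains[0]
    if chain_id not in chains:
        raise TopologyError(
            f"{path}: chain {chain_id!r} not found (available: {chains})")
    arr = arr[arr.chain_id == chain_id]
    arr = arr[~np.isin(arr.element, ("H", "D"))]

    residues: List[ResidueAtoms] = []
    missing = []
    for res_id in dict.fromkeys(arr.res_id):
        sub = arr[arr.res_id == res_id]
        ca = sub[sub.atom_name == "CA"]
        if ca.array_length() == 0:
            missing.append(int(res_id))
            continue
        # PDB coordinates carry exactly three decimals; re-quantising after
        # the reader's float32 pass restores the printed values exactly
        residues.append(ResidueAtoms(
            res_id=int(res_id), name=str(sub.res_name[0]),
            ca=np.round(np.array(ca.coord[0], dtype=float), 3),
            heavy=np.round(np.array(sub.coord, dtype=float), 3)))
    if missing:
        raise TopologyError(
            f"{path} chain {chain_id}: residues without C-alpha: {missing}")
    return residues


def build_native_topology(residues: List[ResidueAtoms],
                          params: ModelParams) -> NativeTopology:
    """Native topology from per-residue heavy atoms (4.5 A contact rule).

    Bond lengths outside 2.7--4.1 A trigger a chain-break warning; outside
    1--6 A the backbone is considered broken and the build fails (the model
    requires an unbroken chain of rigid sticks).
    """
    if len(residues) < 4:
        raise TopologyError("need at least 4 residues")
    ca = np.array([r.ca for r in residues])
    bonds = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    bad = np.where((bonds < _BOND_HARD[0]) | (bonds > _BOND_HARD[1]))[0]
    if bad.size:
        raise TopologyError(
            "backbone break: C-alpha bond lengths outside 1-6 A after "
            f"residues {[residues[i].res_id for i in bad]}")
    odd = np.where((bonds < _BOND_WARN[0]) | (bonds > _BOND_WARN[1]))[0]
    if odd.size:
        warnings.warn(
            "unusual C-alpha bond lengths (possible chain irregularity) "
            f"after residues {[residues[i].res_id for i in odd]}",
            stacklevel=2)
    pairs = []
    n = len(residues)
    for i in range(n):
        hi = residues[i].heavy
        for j in range(i + 2, n):
            d2 = np.min(np.sum(
                (hi[:, None, :] - residues[j].heavy[None, :, :]) ** 2,
                axis=-1))
            if d2 <= params.contact_cutoff ** 2:
                pairs.append((i, j))
    topo = NativeTopology.from_coords(
        ca, pairs,
        residue_numbers=np.array([r.res_id for r in residues]),
        metadata={"contact_rule": HEAVY_ATOM_RULE,
                  "contact_cutoff": params.contact_cutoff})
    topo.validate()
    return topo


def extend_tails(topo: NativeTopology,
                 n_added_per_terminus: int) -> NativeTopology:
    """Append straight tail beads at both termini (engineered variants).

    Each tail continues the mean direction of the three terminal native
    bonds, spaced 3.8 A, emulating alanine extensions built "in an
    approximate straight line".  Original contacts and native chiralities
    are preserved; added beads only gain contacts if they fall within the
    topology's contact rule distance of another bead's C-alpha (by
    construction of the straight-line placement, normally none), so the
    tails add a topological burden without changing the folded state's
    energetic stability.
    """
    k = int(n_added_per_terminus)
    if k < 0:
        raise ValueError("n_added_per_terminus must be >= 0")
    if k == 0:
        return topo
    coords = topo.native_coords
    spacing = 3.8

    def tail_dir(end_bonds):
        units = end_bonds / np.linalg.norm(end_bonds, axis=1, keepdims=True)
        d = units.mean(axis=0)
        return d / np.linalg.norm(d)

    bonds = np.diff(coords, axis=0)
    d_n = tail_dir(-bonds[:3][::-1])          # points beyond bead 0
    d_c = tail_dir(bonds[-3:])                # points beyond bead N-1
    head = coords[0] + d_n * spacing * np.arange(k, 0, -1)[:, None]
    tail = coords[-1] + d_c * spacing * np.arange(1, k + 1)[:, None]
    new_coords = np.vstack([head, coords, tail])

    pairs = [(int(i) + k, int(j) + k) for i, j in zip(topo.ci, topo.cj)]
    # an added bead is a lone "heavy atom": it contacts another bead only
    # within the heavy-atom cutoff of that bead's C-alpha (expected: none
    # for a straight-line placement), never via the wider C-alpha proxy
    cutoff = topo.metadata.get("contact_cutoff", 4.5)
    n_new = new_coords.shape[0]
    new_idx = set(range(k)) | set(range(n_new - k, n_new))
    for i in sorted(new_idx):
        for j in range(n_new):
            if abs(i - j) < 2:
                continue
            if j in new_idx and j < i:
                continue  # new-new pair already visited from the other side
            if np.linalg.norm(new_coords[i] - new_coords[j]) <= cutoff:
                pairs.append((min(i, j), max(i, j)))

    first = int(topo.residue_numbers[0])
    last = int(topo.residue_numbers[-1])
    res_nums = np.concatenate([
        np.arange(first - k, first),
        topo.residue_numbers,
        np.arange(last + 1, last + k + 1)])
    meta = dict(topo.metadata)
    meta["tail_beads_per_terminus"] = meta.get("tail_beads_per_terminus", 0) + k
    return NativeTopology.from_coords(new_coords, pairs,
                                      residue_numbers=res_nums,
                                      metadata=meta)


def tail_variant_name(topo: NativeTopology, base_n_tail: int = 10,
                      base_c_tail: int = 10) -> str:
    """Engineered-variant label, e.g. 5 added per terminus -> 'N15C15'."""
    k = topo.metadata.get("tail_beads_per_terminus", 0)
    return f"N{base_n_tail + k}C{base_c_tail + k}"


# ---------------------------------------------------------------------------
# interchange formats

def topology_to_json(topo: NativeTopology, path=None) -> str:
    """Serialise a topology (plus manifest data) to a JSON text archive."""
    doc = {
        "format": "knotfold-topology-1",
        "n_beads": topo.n_beads,
        "n_contacts": topo.n_contacts,
        "native_coords": topo.native_coords.tolist(),
        "contacts": [[int(i), int(j)] for i, j in zip(topo.ci, topo.cj)],
        "bond_lengths": topo.bond_lengths.tolist(),
        "residue_numbers": topo.residue_numbers.tolist(),
        "metadata": topo.metadata,
    }
    text = json.dumps(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def topology_from_json(src) -> NativeTopology:
    """Load a topology archive written by :func:`topology_to_json`."""
    if isinstance(src, (str, bytes)) and not str(src).lstrip().startswith("{"):
        with open(src) as fh:
            doc = json.load(fh)
    elif isinstance(src, (str, bytes)):
        doc = json.loads(src)
    else:
        doc = json.load(src)
    if doc.get("format") != "knotfold-topology-1":
        raise TopologyError("not a knotfold topology archive")
    topo = NativeTopology.from_coords(
        np.array(doc["native_coords"], dtype=float),
        [tuple(p) for p in doc["contacts"]],
        residue_numbers=np.array(doc["residue_numbers"]),
        metadata=doc.get("metadata", {}))
    topo.validate()
    return topo


def write_calpha_pdb(coords: np.ndarray, path,
                     residue_numbers: Optional[np.ndarray] = None,
                     chain_id: str = "A"):
    """Write a C-alpha-only PDB file (coordinates quantised to 0.001 A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if residue_numbers is None:
        residue_numbers = np.arange(1, n + 1)
    arr = struc.AtomArray(n)
    arr.coord = np.round(coords, 3)
    arr.chain_id = np.full(n, chain_id)
    arr.res_id = np.asarray(residue_numbers, dtype=int)
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_calpha_trace(path, chain_id: Optional[str] = None,
                      model_index: int = 0):
    """C-alpha coordinates and residue numbers from a structure file."""
    residues = load_structure(path, chain_id, model_index)
    ca = np.array([r.ca for r in residues])
    nums = np.array([r.res_id for r in residues])
    return ca, nums


def write_xyz(coords: np.ndarray, path, comment: str = ""):
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{coords.shape[0]}\n{comment}\n")
        for x, y, z in coords:
            fh.write(f"CA {float(x):.17g} {float(y):.17g} {float(z):.17g}\n")


def read_xyz(path) -> np.ndarray:
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        rows = [fh.readline().split()[1:4] for _ in range(n)]
    return np.array(rows, dtype=float)
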