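"""Molecular structures: PDB I/O, rigid transforms and geometric observables.

Coordinates are stored in Å throughout; nanometre conversions happen only at
the DEER boundary. Residue numbering and chain identifiers follow the source
file verbatim so that sites like ``A:117`` address the same residue as in the
deposited entry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, EmptyStructureError, FormatError

__all__ = [
    "Atom",
    "Structure",
    "RigidTransform",
    "read_pdb",
    "write_pdb",
    "radius_of_gyration",
    "pair_distance_histogram",
    "kabsch_superpose",
    "kabsch_rmsd",
]


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus a position in Å."""

    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    mass: float
    hetatm: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.mass > 0:
            raise ValueError("atom mass must be positive")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_point(cls, axis: np.ndarray, angle: float,
                          point: np.ndarray) -> "RigidTransform":
        """Rotation by ``angle`` about the line through ``point`` along ``axis``."""
        from scipy.spatial.transform import Rotation

        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        R = Rotation.from_rotvec(angle * u).as_matrix()
        p = np.asarray(point, dtype=float)
        return cls(R, p - R @ p)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# average atomic weights for elements common in protein structures
_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938,
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _element_from_name(atom_name: str) -> str:
    name = atom_name.strip()
    # two-letter elements in PDB names start in column 13; heuristics suffice
    if name[:2].upper() in ("FE", "ZN", "MG", "NA", "CL", "MN", "SE") and len(name) <= 2:
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _element_mass(element: str) -> float:
    try:
        w = gemmi.Element(element).weight
        if w > 0:
            return w
    except Exception:
        pass
    return _ELEMENT_MASS.get(element.upper(), 12.011)


def _element_electrons(element: str) -> int:
    try:
        z = gemmi.Element(element).atomic_number
        if z > 0:
            return z
    except Exception:
        pass
    return 6


class Structure:
    """Columnar container of atoms with chain/residue identity preserved.

    Atoms keep the order of the source; ``(chain_id, residue_number, name)``
    is unique within a structure.
    """

    def __init__(self, atoms):
        atoms = list(atoms)
        if not atoms:
            raise EmptyStructureError("structure must contain at least one atom")
        self.atom_names = np.array([a.name for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.residue_numbers = np.array([a.residue_number for a in atoms], dtype=int)
        self.residue_names = np.array([a.residue_name for a in atoms])
        self.chain_ids = np.array([a.chain_id for a in atoms])
        self.positions = np.array([a.position for a in atoms], dtype=float)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.hetatm = np.array([a.hetatm for a in atoms], dtype=bool)
        keys = set(zip(self.chain_ids.tolist(), self.residue_numbers.tolist(),
                       self.atom_names.tolist()))
        if len(keys) != len(atoms):
            raise FormatError("(chain, residue number, atom name) must be unique")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, *, atom_names, elements, residue_numbers, residue_names,
                    chain_ids, positions, masses=None, hetatm=None) -> "Structure":
        n = len(atom_names)
        positions = np.asarray(positions, dtype=float)
        if masses is None:
            masses = [_element_mass(e) for e in elements]
        if hetatm is None:
            hetatm = [False] * n
        atoms = [
            Atom(atom_names[i], elements[i], int(residue_numbers[i]),
                 residue_names[i], chain_ids[i], positions[i], float(masses[i]),
                 bool(hetatm[i]))
            for i in range(n)
        ]
        return cls(atoms)

    def __len__(self) -> int:
        return len(self.atom_names)

    def atoms(self):
        for i in range(len(self)):
            yield Atom(self.atom_names[i], self.elements[i],
                       int(self.residue_numbers[i]), self.residue_names[i],
                       self.chain_ids[i], self.positions[i].copy(),
                       float(self.masses[i]), bool(self.hetatm[i]))

    # -- selection ------------------------------------------------------------

    @property
    def chains(self):
        seen = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen

    def mask(self, *, chain=None, residue_number=None, atom_name=None,
             include_het=True) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain_ids == chain
        if residue_number is not None:
            m &= self.residue_numbers == residue_number
        if atom_name is not None:
            m &= self.atom_names == atom_name
        if not include_het:
            m &= ~self.hetatm
        return m

    def subset(self, mask: np.ndarray) -> "Structure":
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptyStructureError("selection matched no atoms")
        return Structure.from_arrays(
            atom_names=self.atom_names[idx], elements=self.elements[idx],
            residue_numbers=self.residue_numbers[idx],
            residue_names=self.residue_names[idx], chain_ids=self.chain_ids[idx],
            positions=self.positions[idx], masses=self.masses[idx],
            hetatm=self.hetatm[idx])

    def atom_position(self, chain: str, residue_number: int, atom_name: str):
        m = self.mask(chain=chain, residue_number=residue_number, atom_name=atom_name)
        idx = np.flatnonzero(m)
        if idx.size == 0:
            return None
        return self.positions[idx[0]].copy()

    def electrons(self) -> np.ndarray:
        return np.array([_element_electrons(e) for e in self.elements], dtype=float)

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    # -- geometry -------------------------------------------------------------

    def transformed(self, T: RigidTransform) -> "Structure":
        new = Structure.from_arrays(
            atom_names=self.atom_names, elements=self.elements,
            residue_numbers=self.residue_numbers, residue_names=self.residue_names,
            chain_ids=self.chain_ids, positions=T.apply(self.positions),
            masses=self.masses, hetatm=self.hetatm)
        return new

    def with_chain_ids(self, mapping: dict) -> "Structure":
        chains = np.array([mapping.get(c, c) for c in self.chain_ids])
        return Structure.from_arrays(
            atom_names=self.atom_names, elements=self.elements,
            residue_numbers=self.residue_numbers, residue_names=self.residue_names,
            chain_ids=chains, positions=self.positions, masses=self.masses,
            hetatm=self.hetatm)

    def merge(self, other: "Structure") -> "Structure":
        return Structure(list(self.atoms()) + list(other.atoms()))

    def centroid(self, weighting: str = "mass") -> np.ndarray:
        w = self.masses if weighting == "mass" else np.ones(len(self))
        return (self.positions * w[:, None]).sum(axis=0) / w.sum()


def apply_transform(s: Structure, T: RigidTransform) -> Structure:
    """Return a copy of ``s`` with every position mapped to R·p + t."""
    return s.transformed(T)


def read_pdb(path, *, model_index: int = 0) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first model of a multi-model entry is taken; for alternate
    locations the highest-occupancy conformer is kept. Elements missing from
    the file are inferred from the atom name.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = st[model_index]
    atoms = []
    for chain in model:
        for residue in chain:
            best = {}
            for at in residue:
                key = at.name
                if key not in best or at.occ > best[key].occ:
                    best[key] = at
            for at in best.values():
                elem = at.element.name if at.element and at.element.name != "X" \
                    else _element_from_name(at.name)
                atoms.append(Atom(
                    name=at.name, element=elem,
                    residue_number=residue.seqid.num, residue_name=residue.name,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    mass=_element_mass(elem),
                    hetatm=(residue.het_flag == "H"),
                ))
    if not atoms:
        raise EmptyStructureError(f"no atoms parsed from {path}")
    return Structure(atoms)


def write_pdb(s: Structure, path) -> None:
    """Write the structure as a standard single-model PDB file."""
    st = gemmi.Structure()
    st.name = "napring"
    model = gemmi.Model("1")
    for cid in s.chains:
        chain = gemmi.Chain(str(cid))
        cm = s.chain_ids == cid
        for resnum in dict.fromkeys(s.residue_numbers[cm].tolist()):
            rm = cm & (s.residue_numbers == resnum)
            res = gemmi.Residue()
            res.seqid = gemmi.SeqId(int(resnum), " ")
            res.name = str(s.residue_names[np.flatnonzero(rm)[0]])
            res.het_flag = "H" if s.hetatm[np.flatnonzero(rm)[0]] else "A"
            for i in np.flatnonzero(rm):
                at = gemmi.Atom()
                at.name = str(s.atom_names[i])
                at.element = gemmi.Element(str(s.elements[i]))
                at.pos = gemmi.Position(*s.positions[i])
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def radius_of_gyration(s: Structure, weighting: str = "mass",
                       include_het: bool = False) -> float:
    """Rg = sqrt(Σ wᵢ|pᵢ − p̄|² / Σ wᵢ) in Å.

    ``weighting`` is ``"mass"``, ``"uniform"`` or ``"electron"``; waters and
    ligands are excluded unless ``include_het``.
    """
    m = s.mask(include_het=include_het)
    pos = s.positions[m]
    if pos.shape[0] < 2:
        raise DegenerateInputError("radius of gyration needs at least 2 atoms")
    if weighting == "mass":
        w = s.masses[m]
    elif weighting == "uniform":
        w = np.ones(pos.shape[0])
    elif weighting == "electron":
        w = s.electrons()[m]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    cen = (pos * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((pos - cen) ** 2).sum(axis=1)).sum() / w.sum()))


def pair_distance_histogram(s: Structure, bin_width: float,
                            weighting: str = "electron",
                            include_het: bool = False):
    """Weighted histogram of all interatomic distances as a :class:`PofR`.

    Weights are products of per-atom scattering weights (electron counts by
    default). ``Dmax`` is the upper edge of the largest occupied bin.
    """
    from .saxs import PofR

    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    m = s.mask(include_het=include_het)
    pos = s.positions[m]
    if pos.shape[0] < 2:
        raise DegenerateInputError("pair histogram needs at least 2 atoms")
    if weighting == "electron":
        w = s.electrons()[m]
    elif weighting == "mass":
        w = s.masses[m]
    elif weighting == "uniform":
        w = np.ones(pos.shape[0])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    d = pdist(pos)
    iu, ju = np.triu_indices(pos.shape[0], k=1)
    pw = w[iu] * w[ju]
    n_bins = int(np.ceil(d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(d, bins=edges, weights=pw)
    occupied = np.flatnonzero(hist > 0)
    dmax = float(edges[occupied[-1] + 1])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PofR(r=centers, p=hist.astype(float), dmax=dmax)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``mobile`` onto ``target``."""
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        from .errors import AlignmentError
        raise AlignmentError("superposition needs >= 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, qc - R @ pc)


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between two point sets after optimal superposition, in Å."""
    T = kabsch_superpose(P, Q)
    diff = T.apply(P) - np.asarray(Q, dtype=float)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))
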