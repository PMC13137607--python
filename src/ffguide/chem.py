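"""Domain types and standard-format I/O.

Ligands are molecular graphs with 3D coordinates (``LigandGraph``), read
from and written to SDF.  Protein pockets are rigid atom sets
(``PocketStructure``) read from PDB/PQR, with per-atom partial charges
taken from the file, from a sidecar CSV, or from a Gasteiger fallback.

Units: coordinates in Å, charges in elementary units, van der Waals well
depths in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "BOND_ORDERS",
    "LigandGraph",
    "PocketStructure",
    "read_ligand",
    "write_ligand",
    "read_pocket",
    "write_pocket",
    "extract_pocket",
    "ELEMENT_VDW_DEFAULTS",
]

#: Supported bond orders.
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RD_TO_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_TO_RD = {v: k for k, v in _RD_TO_ORDER.items()}

#: MMFF94-style (R* [Å], ε [kcal/mol]) diagonal nonbonded parameters for
#: common elements, used for pocket atoms whose molecular environment
#: cannot be perceived.  Values are the diagonal pair parameters of
#: representative MMFF94 atom types for each element.
ELEMENT_VDW_DEFAULTS = {
    "H": (2.9698, 0.021574),
    "C": (3.9377, 0.067797),
    "N": (3.8900, 0.072150),
    "O": (3.5581, 0.076255),
    "S": (4.3694, 0.268083),
    "P": (3.7339, 0.259570),
    "F": (2.9920, 0.080149),
    "Cl": (4.0886, 0.276333),
    "Br": (4.3317, 0.388868),
    "I": (4.7167, 0.551385),
}


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class LigandGraph:
    """A small molecule: 3D coordinates plus a typed bond graph.

    Attributes
    ----------
    coords : (N, 3) float array, Å
    elements : list of chemical symbols, length N
    formal_charges : (N,) int array, elementary units
    bonds : list of (i, j, order) with order in :data:`BOND_ORDERS`
    name : molecule title
    """

    coords: np.ndarray
    elements: list[str]
    formal_charges: np.ndarray
    bonds: list[tuple[int, int, str]]
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.formal_charges = np.asarray(self.formal_charges, dtype=int)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        seen = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")
            if order not in BOND_ORDERS:
                raise ValueError(f"unknown bond order {order!r}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i}, {j})")
            seen.add(key)
        if n > 1 and not self._connected():
            warnings.warn(f"molecular graph {self.name!r} is disconnected",
                          stacklevel=3)

    def _connected(self) -> bool:
        n = len(self.elements)
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == n

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_heavy(self) -> int:
        return sum(1 for e in self.elements if e != "H")

    def with_coords(self, coords: np.ndarray) -> "LigandGraph":
        """Copy of this graph with replaced coordinates."""
        return replace(self, coords=np.array(coords, dtype=float))

    # -- RDKit bridge -------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, conf_id: int = -1) -> "LigandGraph":
        if mol.GetNumConformers() == 0:
            raise FormatError("molecule has no conformer (no 3D coordinates)")
        conf = mol.GetConformer(conf_id)
        coords = np.array(conf.GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = np.array([a.GetFormalCharge() for a in mol.GetAtoms()])
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RD_TO_ORDER[b.GetBondType()])
            for b in mol.GetBonds()
        ]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return cls(coords, elements, charges, bonds, name)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for el, q in zip(self.elements, self.formal_charges):
            atom = Chem.Atom(el)
            atom.SetFormalCharge(int(q))
            atom.SetNoImplicit(True)
            rw.AddAtom(atom)
        for i, j, order in self.bonds:
            rw.AddBond(i, j, _ORDER_TO_RD[order])
        mol = rw.GetMol()
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, [float(v) for v in xyz])
        mol.AddConformer(conf)
        mol.SetProp("_Name", self.name)
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol


@dataclass
class PocketStructure:
    """A rigid set of protein atoms with nonbonded parameters.

    Attributes
    ----------
    coords : (M, 3) float array, Å
    elements : chemical symbols, length M
    partial_charges : (M,) float, elementary units
    vdw_epsilon : (M,) float, kcal/mol; diagonal MMFF94-style well depth
    vdw_rstar : (M,) float, Å; diagonal MMFF94-style minimum distance
    residue_ids : length-M labels, e.g. ``"A:SER:17"``
    """

    coords: np.ndarray
    elements: list[str]
    partial_charges: np.ndarray
    vdw_epsilon: np.ndarray
    vdw_rstar: np.ndarray
    residue_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.partial_charges = np.asarray(self.partial_charges, dtype=float)
        self.vdw_epsilon = np.asarray(self.vdw_epsilon, dtype=float)
        self.vdw_rstar = np.asarray(self.vdw_rstar, dtype=float)
        m = len(self.elements)
        if not self.residue_ids:
            self.residue_ids = ["X:UNK:1"] * m
        if self.coords.shape != (m, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({m}, 3)")
        if len(self.residue_ids) != m:
            raise ValueError("residue_ids length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite pocket coordinates")
        if not np.all(np.isfinite(self.partial_charges)):
            raise ValueError("non-finite pocket charges")
        if np.any(self.vdw_epsilon <= 0) or np.any(self.vdw_rstar <= 0):
            raise ValueError("van der Waals parameters must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def subset(self, idx: np.ndarray) -> "PocketStructure":
        idx = np.asarray(idx)
        return PocketStructure(
            self.coords[idx],
            [self.elements[i] for i in idx],
            self.partial_charges[idx],
            self.vdw_epsilon[idx],
            self.vdw_rstar[idx],
            [self.residue_ids[i] for i in idx],
        )


# ---------------------------------------------------------------------
# Ligand I/O


def read_ligand(path: str) -> LigandGraph:
    """Read the first record of an SDF file into a :class:`LigandGraph`.

    Aromatic bond flags from the file are preserved.  Raises
    :class:`FormatError` if the record does not parse or carries only 2D
    coordinates.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mol = next(iter(supplier), None)
    if mol is None:
        raise FormatError(f"could not parse SDF record from {path}")
    conf = mol.GetConformer()
    if not conf.Is3D() and _looks_planar(np.array(conf.GetPositions())):
        raise FormatError(f"{path} carries 2D-only coordinates")
    return LigandGraph.from_rdkit(mol)


def _looks_planar(coords: np.ndarray) -> bool:
    return coords.shape[0] > 3 and np.allclose(coords[:, 2], 0.0)


def write_ligand(ligand: LigandGraph, path: str) -> None:
    """Write a ligand as a single-record V2000 SDF file."""
    mol = ligand.to_rdkit()
    writer = Chem.SDWriter(str(path))
    writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------
# Pocket I/O


def read_pocket(path: str, charges: str | None = None) -> PocketStructure:
    """Read a protein/pocket from a PDB or PQR file.

    Partial charges are resolved in order of preference: a sidecar CSV
    (columns ``atom_serial, charge``), the PQR charge column, or a
    Gasteiger fallback computed on the perceived molecular graph.  vdW
    parameters come from MMFF94 typing of the perceived graph where
    possible, else from :data:`ELEMENT_VDW_DEFAULTS`.
    """
    path = str(path)
    if path.lower().endswith(".pqr"):
        coords, elements, res_ids, serials, q = _parse_pqr(path)
    else:
        coords, elements, res_ids, serials = _parse_pdb(path)
        q = None
    if len(elements) == 0:
        raise FormatError(f"no ATOM/HETATM records in {path}")

    if charges is not None:
        q = _sidecar_charges(charges, serials)
    if q is None:
        q = _gasteiger_charges(path, len(elements))

    eps, rstar = _pocket_vdw_params(path, elements)
    return PocketStructure(coords, elements, q, eps, rstar, res_ids)


def _parse_pdb(path: str):
    import biotite.structure.io.pdb as pdb

    pf = pdb.PDBFile.read(path)
    try:
        arr = pf.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # empty or malformed file
        raise FormatError(f"could not parse PDB {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"no ATOM/HETATM records in {path}")
    elements = [e.capitalize() for e in arr.element]
    if any(not e for e in elements):
        raise FormatError(f"{path}: atoms with unguessable element")
    res_ids = [
        f"{c}:{rn}:{ri}" for c, rn, ri in zip(arr.chain_id, arr.res_name, arr.res_id)
    ]
    return (np.array(arr.coord, dtype=float), elements, res_ids,
            [int(s) for s in arr.atom_id])


def _parse_pqr(path: str):
    # PQR: PDB-like whitespace-separated records with charge and radius
    # replacing occupancy/B-factor.  Neither biotite nor biopython reads
    # the charge column, so parse by hand.
    coords, elements, res_ids, serials, q = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            # name chain? PQR from pdb2pqr: rec ser name res [chain] resnum x y z q r
            if len(parts) == 11:
                _, ser, name, res, chain, resnum, x, y, z, qq, _r = parts
            elif len(parts) == 10:
                _, ser, name, res, resnum, x, y, z, qq, _r = parts
                chain = "X"
            else:
                raise FormatError(f"unrecognized PQR line: {line.rstrip()}")
            coords.append([float(x), float(y), float(z)])
            el = _element_from_name(name)
            elements.append(el)
            res_ids.append(f"{chain}:{res}:{resnum}")
            serials.append(int(ser))
            q.append(float(qq))
    return (np.array(coords, dtype=float).reshape(-1, 3), elements, res_ids,
            serials, np.array(q, dtype=float))


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if stripped[:2].capitalize() in ELEMENT_VDW_DEFAULTS:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _sidecar_charges(table_path: str, serials: list[int]) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(table_path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        ser_col, q_col = cols["atom_serial"], cols["charge"]
    except KeyError as exc:
        raise FormatError(
            "sidecar charge table needs 'atom_serial' and 'charge' columns"
        ) from exc
    lookup = dict(zip(df[ser_col].astype(int), df[q_col].astype(float)))
    try:
        return np.array([lookup[s] for s in serials], dtype=float)
    except KeyError as exc:
        raise FormatError(f"sidecar table missing charge for atom serial {exc}")


def _perceive_mol(path: str) -> Chem.Mol | None:
    if path.lower().endswith(".pqr"):
        return None
    try:
        mol = Chem.MolFromPDBFile(path, removeHs=False, sanitize=False,
                                  proximityBonding=True)
        if mol is not None:
            Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def _gasteiger_charges(path: str, n: int) -> np.ndarray:
    mol = _perceive_mol(path)
    if mol is not None and mol.GetNumAtoms() == n:
        try:
            AllChem.ComputeGasteigerCharges(mol)
            q = np.array([a.GetDoubleProp("_GasteigerCharge")
                          for a in mol.GetAtoms()])
            if np.all(np.isfinite(q)):
                return q
        except Exception:
            pass
    warnings.warn(f"charge fallback failed for {path}; assigning zero charges",
                  stacklevel=3)
    return np.zeros(n)


def _pocket_vdw_params(path: str, elements: list[str]):
    n = len(elements)
    mol = _perceive_mol(path)
    if mol is not None and mol.GetNumAtoms() == n:
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is not None:
            rstar = np.empty(n)
            eps = np.empty(n)
            for i in range(n):
                _, _, rstar[i], eps[i] = props.GetMMFFVdWParams(i, i)
            return eps, rstar
    pairs = [ELEMENT_VDW_DEFAULTS.get(e) for e in elements]
    if any(p is None for p in pairs):
        missing = sorted({e for e, p in zip(elements, pairs) if p is None})
        raise FormatError(f"no default vdW parameters for element(s) {missing}")
    arr = np.array(pairs)
    return arr[:, 1].copy(), arr[:, 0].copy()


def write_pocket(pocket: PocketStructure, path: str) -> None:
    """Write a pocket as PDB; charges go to a CSV sidecar next to it."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arr = struc.AtomArray(pocket.n_atoms)
    arr.coord = pocket.coords.astype(np.float32)
    for i, (el, rid) in enumerate(zip(pocket.elements, pocket.residue_ids)):
        chain, res_name, res_id = (rid.split(":") + ["1"])[:3]
        arr.chain_id[i] = chain[:4]
        arr.res_name[i] = res_name[:5]
        arr.res_id[i] = int("".join(ch for ch in res_id if ch.isdigit()) or 1)
        arr.atom_name[i] = f"{el}{i % 100}"
        arr.element[i] = el.upper()
    arr.hetero[:] = False
    pf = pdb.PDBFile()
    pf.set_structure(arr)
    pf.write(str(path))
    import pandas as pd

    pd.DataFrame(
        {"atom_serial": np.arange(1, pocket.n_atoms + 1),
         "charge": pocket.partial_charges}
    ).to_csv(str(path) + ".charges.csv", index=False)


# ---------------------------------------------------------------------
# Pocket extraction


def extract_pocket(
    protein: PocketStructure,
    native_ligand: LigandGraph,
    radius: float = 3.5,
    min_atoms: int = 10,
) -> PocketStructure:
    """Select binding-site residues around a native ligand.

    A residue is kept iff it has at least one atom within ``radius`` Å
    (closed bound, ≤) of any ligand atom *and* consists of strictly more
    than ``min_atoms`` atoms.  Raises ``ValueError`` when no residue
    qualifies.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(native_ligand.coords)
    dmin = tree.query(protein.coords, k=1)[0]
    res_ids = np.array(protein.residue_ids)
    keep: list[int] = []
    for rid in dict.fromkeys(protein.residue_ids):  # preserve file order
        mask = res_ids == rid
        if mask.sum() > min_atoms and np.min(dmin[mask]) <= radius:
            keep.extend(np.flatnonzero(mask))
    if not keep:
        raise ValueError(
            f"no pocket residues within {radius} Å with > {min_atoms} atoms"
        )
    return protein.subset(np.array(sorted(keep)))
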