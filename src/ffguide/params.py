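"""MMFF94 parameter acquisition.

Atom typing and parameter lookup are delegated to RDKit's MMFF94
implementation; the resulting per-molecule tables are serialized into a
neutral, toolkit-independent :class:`MMFFParameterSet` of NumPy arrays
over which the energy and gradient kernels in :mod:`ffguide.intra` and
:mod:`ffguide.cross` operate.

Term enumeration mirrors the reference implementation exactly:

* bonds — every bond;
* angles — every i–j–k with i, k distinct neighbours of j (linear
  centres flagged via θ₀ = 180°);
* stretch–bends — non-linear angles with tabulated coupling constants;
* out-of-plane — the three Wilson angles at every tricoordinate centre
  with tabulated constants;
* torsions — every i–j–k–l bonded path with i ≠ l (paths inside
  three-membered rings carry no parameters and are skipped);
* nonbonded — all atom pairs except 1-2 and 1-3; 1-4 pairs (graph
  distance exactly 3) are flagged for the 0.75 electrostatic scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import LigandGraph

__all__ = ["MMFFParameterSet", "ParameterizationError", "parameterize"]


class ParameterizationError(RuntimeError):
    """MMFF94 atom typing or parameter lookup failed.

    Carries ``atom_index`` (may be ``None`` when the failing atom cannot
    be localized).
    """

    def __init__(self, message: str, atom_index: int | None = None):
        super().__init__(message)
        self.atom_index = atom_index


@dataclass
class MMFFParameterSet:
    """Complete MMFF94 parameter tables for one molecule.

    Index arrays refer to atom positions in the source graph.  Bond
    force constants ``bond_kb`` are in md/Å, reference lengths in Å,
    angle constants in md·Å/rad² against reference angles in degrees,
    torsion amplitudes in kcal/mol, charges in elementary units.
    """

    n_atoms: int
    # bond stretching
    bond_idx: np.ndarray          # (B, 2) int
    bond_kb: np.ndarray           # (B,)
    bond_r0: np.ndarray           # (B,)
    # angle bending (i, j, k), centre j
    angle_idx: np.ndarray         # (A, 3) int
    angle_ka: np.ndarray          # (A,)
    angle_theta0: np.ndarray      # (A,) degrees
    angle_linear: np.ndarray      # (A,) bool
    # stretch-bend coupling, subset of angles
    sb_idx: np.ndarray            # (S, 3) int
    sb_kba_ijk: np.ndarray        # (S,)
    sb_kba_kji: np.ndarray        # (S,)
    sb_r0_ij: np.ndarray          # (S,)
    sb_r0_kj: np.ndarray          # (S,)
    sb_theta0: np.ndarray         # (S,) degrees
    # out-of-plane (i, j, k; l), centre j, l out of plane
    oop_idx: np.ndarray           # (O, 4) int
    oop_koop: np.ndarray          # (O,)
    # torsions
    torsion_idx: np.ndarray       # (T, 4) int
    torsion_v: np.ndarray         # (T, 3) V1, V2, V3 kcal/mol
    # nonbonded: all included intramolecular pairs with exact pair params
    nb_idx: np.ndarray            # (P, 2) int
    nb_eps: np.ndarray            # (P,) kcal/mol
    nb_rstar: np.ndarray          # (P,) Å
    nb_is14: np.ndarray           # (P,) bool
    # per-atom quantities
    charges: np.ndarray           # (N,) e
    vdw_eps: np.ndarray           # (N,) diagonal well depth, kcal/mol
    vdw_rstar: np.ndarray         # (N,) diagonal R*, Å
    # exclusion topology (kept for serialization/inspection)
    excluded_pairs: np.ndarray    # (E, 2) int, 1-2 and 1-3 pairs
    pairs_14: np.ndarray          # (F, 2) int

    def __post_init__(self) -> None:
        bonded = {frozenset(p) for p in map(tuple, self.bond_idx)}
        covered = {frozenset(p) for p in map(tuple, self.excluded_pairs)}
        if not bonded <= covered:
            raise ValueError("every bonded pair must appear in the exclusions")
        one4 = {frozenset(p) for p in map(tuple, self.pairs_14)}
        if covered & one4:
            raise ValueError("1-4 pairs must be disjoint from exclusions")
        for name in ("charges", "vdw_eps", "vdw_rstar"):
            if len(getattr(self, name)) != self.n_atoms:
                raise ValueError(f"{name} length != n_atoms")

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "MMFFParameterSet":
        raw = json.loads(text)
        kwargs = {}
        for f, value in raw.items():
            if f == "n_atoms":
                kwargs[f] = int(value)
                continue
            dtype = bool if f in ("angle_linear", "nb_is14") else (
                int if f.endswith("idx") or f in ("excluded_pairs", "pairs_14")
                else float)
            arr = np.asarray(value, dtype=dtype)
            if f.endswith("idx") or f in ("excluded_pairs", "pairs_14"):
                width = {"bond_idx": 2, "angle_idx": 3, "sb_idx": 3,
                         "oop_idx": 4, "torsion_idx": 4, "nb_idx": 2,
                         "excluded_pairs": 2, "pairs_14": 2}[f]
                arr = arr.reshape(-1, width)
            if f == "torsion_v":
                arr = np.asarray(value, dtype=float).reshape(-1, 3)
            kwargs[f] = arr
        return cls(**kwargs)


def _neighbour_lists(n: int, bonds) -> list[list[int]]:
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    return [sorted(v) for v in nbrs]


def parameterize(mol: LigandGraph | Chem.Mol) -> MMFFParameterSet:
    """Assign MMFF94 parameters to a molecule.

    Accepts a :class:`~ffguide.chem.LigandGraph` or an RDKit ``Mol``
    with a 3D conformer.  Molecules with implicit hydrogens are
    protonated deterministically before typing (MMFF94 requires explicit
    hydrogens).  Raises :class:`ParameterizationError` when sanitization
    or atom typing fails.
    """
    if isinstance(mol, LigandGraph):
        try:
            rd = mol.to_rdkit()
        except Exception as exc:
            raise ParameterizationError(f"molecule does not sanitize: {exc}")
    else:
        rd = Chem.Mol(mol)

    if any(a.GetNumImplicitHs() > 0 for a in rd.GetAtoms()):
        rd = Chem.AddHs(rd, addCoords=True)

    props = AllChem.MMFFGetMoleculeProperties(rd)
    if props is None:
        bad = _first_untypable_atom(rd)
        raise ParameterizationError(
            f"MMFF94 atom typing failed (atom {bad})", atom_index=bad)

    n = rd.GetNumAtoms()
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rd.GetBonds()]
    nbrs = _neighbour_lists(n, bonds)

    bond_idx, bond_kb, bond_r0 = [], [], []
    bond_lookup: dict[frozenset, float] = {}
    for i, j in bonds:
        res = props.GetMMFFBondStretchParams(rd, i, j)
        if res is None:
            raise ParameterizationError(f"no bond parameters for ({i}, {j})",
                                        atom_index=i)
        _, kb, r0 = res
        bond_idx.append((i, j))
        bond_kb.append(kb)
        bond_r0.append(r0)
        bond_lookup[frozenset((i, j))] = r0

    angle_idx, angle_ka, angle_t0, angle_lin = [], [], [], []
    sb_idx, sb1, sb2, sbr1, sbr2, sbt0 = [], [], [], [], [], []
    for j in range(n):
        ns = nbrs[j]
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                i, k = ns[a], ns[b]
                res = props.GetMMFFAngleBendParams(rd, i, j, k)
                if res is None:
                    continue
                _, ka, t0 = res
                linear = abs(t0 - 180.0) < 1e-6
                angle_idx.append((i, j, k))
                angle_ka.append(ka)
                angle_t0.append(t0)
                angle_lin.append(linear)
                if linear:
                    continue
                sb = props.GetMMFFStretchBendParams(rd, i, j, k)
                if sb is None:
                    continue
                _, kba_ijk, kba_kji = sb
                sb_idx.append((i, j, k))
                sb1.append(kba_ijk)
                sb2.append(kba_kji)
                sbr1.append(bond_lookup[frozenset((i, j))])
                sbr2.append(bond_lookup[frozenset((k, j))])
                sbt0.append(t0)

    oop_idx, oop_k = [], []
    for j in range(n):
        if len(nbrs[j]) != 3:
            continue
        i, k, l = nbrs[j]
        for a, b, c in ((i, k, l), (i, l, k), (k, l, i)):
            res = props.GetMMFFOopBendParams(rd, a, j, b, c)
            if res is None:
                continue
            oop_idx.append((a, j, b, c))
            oop_k.append(res)

    torsion_idx, torsion_v = [], []
    for j, k in bonds:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l == j or l == i:
                    continue
                res = props.GetMMFFTorsionParams(rd, i, j, k, l)
                if res is None:
                    continue
                _, v1, v2, v3 = res
                torsion_idx.append((i, j, k, l))
                torsion_v.append((v1, v2, v3))

    excluded = {frozenset(b) for b in bonds}
    excluded |= {frozenset((i, k)) for (i, j, k) in angle_idx}
    # 1-3 pairs exist even where no angle parameters were found
    for j in range(n):
        ns = nbrs[j]
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                excluded.add(frozenset((ns[a], ns[b])))
    one4 = set()
    for j, k in bonds:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l in (j, i):
                    continue
                pair = frozenset((i, l))
                if pair not in excluded:
                    one4.add(pair)

    nb_idx, nb_eps, nb_rstar, nb_is14 = [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset((i, j))
            if pair in excluded:
                continue
            _, _, rstar, eps = props.GetMMFFVdWParams(i, j)
            nb_idx.append((i, j))
            nb_eps.append(eps)
            nb_rstar.append(rstar)
            nb_is14.append(pair in one4)

    charges = np.array([props.GetMMFFPartialCharge(i) for i in range(n)])
    vdw_eps = np.empty(n)
    vdw_rstar = np.empty(n)
    for i in range(n):
        _, _, vdw_rstar[i], vdw_eps[i] = props.GetMMFFVdWParams(i, i)

    def _arr(x, dtype=float, width=None):
        a = np.asarray(x, dtype=dtype)
        if width is not None:
            a = a.reshape(-1, width)
        return a

    return MMFFParameterSet(
        n_atoms=n,
        bond_idx=_arr(bond_idx, int, 2),
        bond_kb=_arr(bond_kb),
        bond_r0=_arr(bond_r0),
        angle_idx=_arr(angle_idx, int, 3),
        angle_ka=_arr(angle_ka),
        angle_theta0=_arr(angle_t0),
        angle_linear=_arr(angle_lin, bool),
        sb_idx=_arr(sb_idx, int, 3),
        sb_kba_ijk=_arr(sb1),
        sb_kba_kji=_arr(sb2),
        sb_r0_ij=_arr(sbr1),
        sb_r0_kj=_arr(sbr2),
        sb_theta0=_arr(sbt0),
        oop_idx=_arr(oop_idx, int, 4),
        oop_koop=_arr(oop_k),
        torsion_idx=_arr(torsion_idx, int, 4),
        torsion_v=_arr(torsion_v, float, 3),
        nb_idx=_arr(nb_idx, int, 2),
        nb_eps=_arr(nb_eps),
        nb_rstar=_arr(nb_rstar),
        nb_is14=_arr(nb_is14, bool),
        charges=charges,
        vdw_eps=vdw_eps,
        vdw_rstar=vdw_rstar,
        excluded_pairs=_arr([tuple(sorted(p)) for p in sorted(excluded, key=sorted)],
                            int, 2),
        pairs_14=_arr([tuple(sorted(p)) for p in sorted(one4, key=sorted)],
                      int, 2),
    )


def _first_untypable_atom(rd: Chem.Mol) -> int | None:
    # locate the offending atom by typing growing fragments is overkill;
    # report the first atom whose element MMFF94 cannot type at all
    supported = {"C", "H", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I",
                 "Fe", "Cu", "Zn", "Li", "Na", "K", "Mg", "Ca"}
    for atom in rd.GetAtoms():
        if atom.GetSymbol() not in supported:
            return atom.GetIdx()
    return None
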