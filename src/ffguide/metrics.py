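"""Pose-quality metrics.

Strain energy is the gap between a conformation's intramolecular MMFF94
energy and that of its force-field-minimized geometry, normalized by
the number of heavy atoms (kcal/mol per heavy atom).  Validity mirrors
the operational definition used to score generated molecules: the
record must parse, sanitize, and yield a complete MMFF94 parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .chem import LigandGraph, PocketStructure
from .guidance import minimize
from .intra import energy_intra
from .params import ParameterizationError, parameterize

__all__ = ["StrainResult", "strain_energy", "validity"]


@dataclass(frozen=True)
class StrainResult:
    """Strain of one pose.

    ``strain_per_heavy`` = (e_generated − e_optimized) / n_heavy.
    """

    e_generated: float
    e_optimized: float
    n_heavy: int
    strain_per_heavy: float


def strain_energy(
    ligand: LigandGraph,
    pocket: PocketStructure | None = None,
    max_iters: int = 500,
) -> StrainResult:
    """Strain energy per heavy atom of a pose.

    By default both the input-pose energy and the relaxation are
    intramolecular MMFF94 (the pose is compared with its own force-field
    minimum).  Passing a ``pocket`` switches to the pocket-conditioned
    total on both sides (conditional strain).
    """
    params = parameterize(ligand)
    if params.n_atoms != ligand.n_atoms:
        raise ParameterizationError(
            "strain energy requires explicit hydrogens on the input graph")
    if pocket is None:
        e_gen = energy_intra(ligand.coords, params).total
    else:
        from .cross import total_energy

        e_gen = total_energy(ligand.coords, params, pocket).total
    result = minimize(ligand, pocket=pocket, max_iters=max_iters)
    e_opt = result.breakdown.total
    n_heavy = ligand.n_heavy
    return StrainResult(
        e_generated=float(e_gen),
        e_optimized=float(e_opt),
        n_heavy=n_heavy,
        strain_per_heavy=float((e_gen - e_opt) / n_heavy),
    )


def validity(ligand_block: str) -> bool:
    """Whether an SDF/MOL record is a usable molecule.

    True iff the block parses, sanitizes, and initializes an MMFF94
    parameter set.  Never raises.
    """
    try:
        mol = Chem.MolFromMolBlock(ligand_block, removeHs=False, sanitize=True)
        if mol is None:
            return False
        parameterize(mol)
        return True
    except Exception:
        return False
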