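"""Protein-conditioned cross-terms.

The MMFF94 nonbonded terms — buffered 14-7 van der Waals and buffered
Coulomb — are extended across the ligand–pocket interface: every
ligand-atom × pocket-atom pair contributes, with no distance cutoff, no
exclusions, and no 1-4 scaling (there are no covalent paths across the
interface).  The pocket is rigid, so gradients are taken with respect to
ligand coordinates only.

Pair parameters combine per-atom diagonal values: R*_ij follows the
MMFF94 arithmetic rule with the non-additive expansion term,

    R*_ij = ½(R*_i + R*_j)(1 + 0.2(1 − exp(−12 γ²))),
    γ = (R*_i − R*_j)/(R*_i + R*_j),

and the well depth scales like the MMFF94 combination,
ε_ij = √(ε_i ε_j)·(R*_i R*_j)³ / R*_ij⁶, which is exact for identical
atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import PocketStructure
from .intra import (EnergyBreakdown, buffered_14_7, buffered_coulomb,
                    energy_and_gradient_intra, energy_intra, gradient_intra)
from .params import MMFFParameterSet

__all__ = ["CrossTermSpec", "combine_vdw_params", "cross_energy",
           "total_energy", "gradient_total"]

_EPS = 1e-12


@dataclass(frozen=True)
class CrossTermSpec:
    """How ligand and pocket nonbonded parameters combine.

    ``dielectric`` is the constant D of the buffered Coulomb term;
    ``buffering_delta`` its distance buffer in Å.
    """

    dielectric: float = 1.0
    buffering_delta: float = 0.05

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


def combine_vdw_params(eps_i, rstar_i, eps_j, rstar_j):
    """MMFF94-style pair parameters from diagonal (ε, R*) values.

    Broadcasts over array inputs; returns ``(eps_ij, rstar_ij)``.
    """
    eps_i, rstar_i = np.asarray(eps_i, float), np.asarray(rstar_i, float)
    eps_j, rstar_j = np.asarray(eps_j, float), np.asarray(rstar_j, float)
    gamma = (rstar_i - rstar_j) / (rstar_i + rstar_j)
    rstar_ij = 0.5 * (rstar_i + rstar_j) * (
        1.0 + 0.2 * (1.0 - np.exp(-12.0 * gamma**2)))
    eps_ij = (np.sqrt(eps_i * eps_j)
              * (rstar_i * rstar_j) ** 3 / rstar_ij**6)
    return eps_ij, rstar_ij


def _cross_pair_arrays(ligand_params: MMFFParameterSet,
                       pocket: PocketStructure):
    eps_ij, rstar_ij = combine_vdw_params(
        ligand_params.vdw_eps[:, None], ligand_params.vdw_rstar[:, None],
        pocket.vdw_epsilon[None, :], pocket.vdw_rstar[None, :])
    qq = ligand_params.charges[:, None] * pocket.partial_charges[None, :]
    return eps_ij, rstar_ij, qq


def cross_energy(
    ligand_coords: np.ndarray,
    ligand_params: MMFFParameterSet,
    pocket: PocketStructure,
    spec: CrossTermSpec = CrossTermSpec(),
) -> tuple[float, float]:
    """Ligand–pocket interaction energy ``(E_vdw, E_q)`` in kcal/mol."""
    (ev, eq), _ = _cross_terms(ligand_coords, ligand_params, pocket, spec,
                               grad=False)
    return ev, eq


def _cross_terms(ligand_coords, ligand_params, pocket, spec, grad):
    if pocket is None or pocket.n_atoms == 0:
        raise ValueError("cross-terms require a non-empty pocket")
    X = np.asarray(ligand_coords, dtype=float)
    if X.shape != (ligand_params.n_atoms, 3):
        raise ValueError(
            f"coords shape {X.shape} != ({ligand_params.n_atoms}, 3)")
    eps_ij, rstar_ij, qq = _cross_pair_arrays(ligand_params, pocket)
    d = X[:, None, :] - pocket.coords[None, :, :]          # (N, M, 3)
    r = np.sqrt(np.maximum(np.einsum("nmk,nmk->nm", d, d), _EPS))
    ev, dev = buffered_14_7(r, eps_ij, rstar_ij, with_derivative=True)
    eq, deq = buffered_coulomb(r, qq, dielectric=spec.dielectric,
                               delta=spec.buffering_delta,
                               with_derivative=True)
    g = None
    if grad:
        g = np.einsum("nm,nmk->nk", (dev + deq) / r, d)
    return (float(ev.sum()), float(eq.sum())), g


def total_energy(
    ligand_coords: np.ndarray,
    ligand_params: MMFFParameterSet,
    pocket: PocketStructure | None = None,
    spec: CrossTermSpec = CrossTermSpec(),
) -> EnergyBreakdown:
    """Full energy: intramolecular MMFF94 plus pocket cross-terms.

    With ``pocket=None`` this is exactly :func:`ffguide.intra.energy_intra`.
    """
    br = energy_intra(ligand_coords, ligand_params)
    if pocket is not None:
        br.cross_vdw, br.cross_electrostatic = cross_energy(
            ligand_coords, ligand_params, pocket, spec)
    return br


def gradient_total(
    ligand_coords: np.ndarray,
    ligand_params: MMFFParameterSet,
    pocket: PocketStructure | None = None,
    spec: CrossTermSpec = CrossTermSpec(),
) -> np.ndarray:
    """∂E_total/∂(ligand coords); the pocket is rigid."""
    g = gradient_intra(ligand_coords, ligand_params)
    if pocket is not None:
        _, gc = _cross_terms(ligand_coords, ligand_params, pocket, spec,
                             grad=True)
        g = g + gc
    return g


def total_energy_and_gradient(ligand_coords, ligand_params, pocket=None,
                              spec=CrossTermSpec()):
    """Breakdown and gradient in one pass (used by samplers/minimizer)."""
    br, g = energy_and_gradient_intra(ligand_coords, ligand_params)
    if pocket is not None:
        (br.cross_vdw, br.cross_electrostatic), gc = _cross_terms(
            ligand_coords, ligand_params, pocket, spec, grad=True)
        g = g + gc
    return br, g
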