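"""Differentiable MMFF94 intramolecular energy.

Pure NumPy kernels over an :class:`~ffguide.params.MMFFParameterSet`:
the seven MMFF94 terms (cubic bond stretch, cubic-corrected angle bend
with a linear special case, stretch–bend coupling, Wilson-angle
out-of-plane bend, three-term torsion cosine series, buffered 14-7 van
der Waals, buffered Coulomb with 0.75 scaling on 1-4 pairs) and their
exact analytic gradients with respect to Cartesian coordinates.

Energies are in kcal/mol, gradients in kcal/mol/Å.  Degenerate
geometries (coincident atoms, collinear angles) are guarded with small
epsilons so that energies and gradients stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .params import MMFFParameterSet

__all__ = ["EnergyBreakdown", "energy_intra", "gradient_intra"]

_D2R = np.pi / 180.0
_R2D = 180.0 / np.pi
_C_MDYNE = 143.9325          # md·Å → kcal/mol
_CS_BOND = -2.0              # bond cubic coefficient, Å⁻¹
_CB_ANGLE = -0.006981317     # angle cubic coefficient, deg⁻¹
_C_ANGLE = 0.5 * _C_MDYNE * _D2R * _D2R
_C_SB = _C_MDYNE * _D2R
_C_OOP = 0.5 * _C_MDYNE * _D2R * _D2R
_ELE_K = 332.0716            # e²/Å → kcal/mol
_ELE_DELTA = 0.05            # electrostatic distance buffering, Å
_SCALE_14 = 0.75
_EPS = 1e-12
_SIN_EPS = 1e-8


@dataclass
class EnergyBreakdown:
    """Per-term energies in kcal/mol.

    ``cross_vdw``/``cross_electrostatic`` are zero when no pocket was
    supplied.  ``total`` always equals the sum of the listed terms.
    """

    bond: float = 0.0
    angle: float = 0.0
    stretch_bend: float = 0.0
    oop: float = 0.0
    torsion: float = 0.0
    vdw: float = 0.0
    electrostatic: float = 0.0
    cross_vdw: float = 0.0
    cross_electrostatic: float = 0.0

    @property
    def total(self) -> float:
        return sum(getattr(self, f.name) for f in fields(self))

    @property
    def intra_total(self) -> float:
        return self.total - self.cross_vdw - self.cross_electrostatic

    def as_dict(self) -> dict[str, float]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["total"] = self.total
        return out


def _check_coords(coords: np.ndarray, params: MMFFParameterSet) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (params.n_atoms, 3):
        raise ValueError(
            f"coords shape {coords.shape} != ({params.n_atoms}, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return coords


def energy_intra(coords: np.ndarray, params: MMFFParameterSet) -> EnergyBreakdown:
    """Single-point MMFF94 intramolecular energy."""
    terms, _ = _intra_terms(_check_coords(coords, params), params, grad=False)
    return EnergyBreakdown(**terms)


def gradient_intra(coords: np.ndarray, params: MMFFParameterSet) -> np.ndarray:
    """∂E/∂coords of the intramolecular energy, kcal/mol/Å."""
    _, g = _intra_terms(_check_coords(coords, params), params, grad=True)
    return g


def energy_and_gradient_intra(coords, params):
    """Energy breakdown and gradient in one pass."""
    terms, g = _intra_terms(_check_coords(coords, params), params, grad=True)
    return EnergyBreakdown(**terms), g


# ---------------------------------------------------------------------
# kernels


def _intra_terms(X: np.ndarray, ps: MMFFParameterSet, grad: bool):
    g = np.zeros_like(X) if grad else None
    terms = {
        "bond": _bond(X, ps, g),
        "stretch_bend": _stretch_bend(X, ps, g),
        "oop": _oop(X, ps, g),
        "torsion": _torsion(X, ps, g),
    }
    terms["angle"] = _angle(X, ps, g)
    terms["vdw"], terms["electrostatic"] = _nonbonded(X, ps, g)
    return terms, g


def _pair_geometry(X, idx):
    d = X[idx[:, 0]] - X[idx[:, 1]]
    r = np.sqrt(np.maximum(np.einsum("ij,ij->i", d, d), _EPS))
    return d, r


def _bond(X, ps, g):
    if len(ps.bond_idx) == 0:
        return 0.0
    d, r = _pair_geometry(X, ps.bond_idx)
    dr = r - ps.bond_r0
    k = 0.5 * _C_MDYNE * ps.bond_kb
    c2 = 7.0 / 12.0 * _CS_BOND * _CS_BOND
    e = k * dr**2 * (1.0 + _CS_BOND * dr + c2 * dr**2)
    if g is not None:
        dedr = k * (2.0 * dr + 3.0 * _CS_BOND * dr**2 + 4.0 * c2 * dr**3)
        f = (dedr / r)[:, None] * d
        np.add.at(g, ps.bond_idx[:, 0], f)
        np.add.at(g, ps.bond_idx[:, 1], -f)
    return float(e.sum())


def _angle_geometry(X, idx):
    """Return unit vectors, norms, cosθ and θ in degrees for i-j-k."""
    u = X[idx[:, 0]] - X[idx[:, 1]]
    v = X[idx[:, 2]] - X[idx[:, 1]]
    nu = np.sqrt(np.maximum(np.einsum("ij,ij->i", u, u), _EPS))
    nv = np.sqrt(np.maximum(np.einsum("ij,ij->i", v, v), _EPS))
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = _R2D * np.arccos(cos)
    return uh, vh, nu, nv, cos, theta


def _dtheta_dx(uh, vh, nu, nv, cos):
    """dθ/dx (radians) for atoms i and k of an i-j-k angle."""
    sin = np.sqrt(np.maximum(1.0 - cos * cos, _SIN_EPS**2))
    di = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
    dk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
    return di, dk


def _angle(X, ps, g):
    if len(ps.angle_idx) == 0:
        return 0.0
    idx = ps.angle_idx
    uh, vh, nu, nv, cos, theta = _angle_geometry(X, idx)
    lin = ps.angle_linear
    dth = theta - ps.angle_theta0
    e = np.where(
        lin,
        _C_MDYNE * ps.angle_ka * (1.0 + cos),
        _C_ANGLE * ps.angle_ka * dth**2 * (1.0 + _CB_ANGLE * dth),
    )
    if g is not None:
        # non-linear part: dE/dθ_deg, chain through dθ_rad/dx
        dedth = np.where(
            lin, 0.0,
            _C_ANGLE * ps.angle_ka * (2.0 * dth + 3.0 * _CB_ANGLE * dth**2))
        di, dk = _dtheta_dx(uh, vh, nu, nv, cos)
        w = (dedth * _R2D)[:, None]
        gi = w * di
        gk = w * dk
        # linear part: dE/dcosθ, chain through dcosθ/dx
        dedcos = np.where(lin, _C_MDYNE * ps.angle_ka, 0.0)[:, None]
        gi += dedcos * (vh - cos[:, None] * uh) / nu[:, None]
        gk += dedcos * (uh - cos[:, None] * vh) / nv[:, None]
        np.add.at(g, idx[:, 0], gi)
        np.add.at(g, idx[:, 2], gk)
        np.add.at(g, idx[:, 1], -(gi + gk))
    return float(e.sum())


def _stretch_bend(X, ps, g):
    if len(ps.sb_idx) == 0:
        return 0.0
    idx = ps.sb_idx
    uh, vh, nu, nv, cos, theta = _angle_geometry(X, idx)
    dth = theta - ps.sb_theta0
    drij = nu - ps.sb_r0_ij
    drkj = nv - ps.sb_r0_kj
    stretch = ps.sb_kba_ijk * drij + ps.sb_kba_kji * drkj
    e = _C_SB * stretch * dth
    if g is not None:
        di, dk = _dtheta_dx(uh, vh, nu, nv, cos)
        w = (_C_SB * stretch * _R2D)[:, None]
        gi = w * di + (_C_SB * ps.sb_kba_ijk * dth)[:, None] * uh
        gk = w * dk + (_C_SB * ps.sb_kba_kji * dth)[:, None] * vh
        np.add.at(g, idx[:, 0], gi)
        np.add.at(g, idx[:, 2], gk)
        np.add.at(g, idx[:, 1], -(gi + gk))
    return float(e.sum())


def _oop(X, ps, g):
    """Wilson out-of-plane: χ is the angle between bond j-c and the
    i-j-k plane for each tricoordinate centre j."""
    if len(ps.oop_idx) == 0:
        return 0.0
    idx = ps.oop_idx
    u = X[idx[:, 0]] - X[idx[:, 1]]
    v = X[idx[:, 2]] - X[idx[:, 1]]
    w = X[idx[:, 3]] - X[idx[:, 1]]
    nu = np.sqrt(np.maximum(np.einsum("ij,ij->i", u, u), _EPS))
    nv = np.sqrt(np.maximum(np.einsum("ij,ij->i", v, v), _EPS))
    nw = np.sqrt(np.maximum(np.einsum("ij,ij->i", w, w), _EPS))
    uh, vh, wh = u / nu[:, None], v / nv[:, None], w / nw[:, None]
    cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, _SIN_EPS**2))
    nvec = np.cross(u, v)
    denom = nu * nv * nw * sin
    s = np.clip(np.einsum("ij,ij->i", nvec, w) / denom, -1.0, 1.0)
    chi = _R2D * np.arcsin(s)
    e = _C_OOP * ps.oop_koop * chi**2
    if g is not None:
        dchids = _R2D / np.sqrt(np.maximum(1.0 - s * s, _SIN_EPS**2))
        dEds = (2.0 * _C_OOP * ps.oop_koop * chi * dchids)[:, None]
        # s = (u×v)·w / (|u||v||w| sinθ_uv); differentiate numerator and
        # denominator separately.
        dthi = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
        dthk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
        cot = (cos / sin)[:, None]
        ddenom_du = (nv * nw * sin)[:, None] * uh + denom[:, None] * cot * dthi
        ddenom_dv = (nu * nw * sin)[:, None] * vh + denom[:, None] * cot * dthk
        ddenom_dw = (nu * nv * sin)[:, None] * wh
        inv = 1.0 / denom[:, None]
        sd = s[:, None]
        gsu = np.cross(v, w) * inv - sd * inv * ddenom_du
        gsv = np.cross(w, u) * inv - sd * inv * ddenom_dv
        gsw = nvec * inv - sd * inv * ddenom_dw
        ga, gb, gc = dEds * gsu, dEds * gsv, dEds * gsw
        np.add.at(g, idx[:, 0], ga)
        np.add.at(g, idx[:, 2], gb)
        np.add.at(g, idx[:, 3], gc)
        np.add.at(g, idx[:, 1], -(ga + gb + gc))
    return float(e.sum())


def _torsion(X, ps, g):
    if len(ps.torsion_idx) == 0:
        return 0.0
    idx = ps.torsion_idx
    b1 = X[idx[:, 1]] - X[idx[:, 0]]
    b2 = X[idx[:, 2]] - X[idx[:, 1]]
    b3 = X[idx[:, 3]] - X[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.sqrt(np.maximum(np.einsum("ij,ij->i", b2, b2), _EPS))
    phi = np.arctan2(
        np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None]),
        np.einsum("ij,ij->i", n1, n2),
    )
    v1, v2, v3 = ps.torsion_v.T
    e = 0.5 * (v1 * (1.0 + np.cos(phi)) + v2 * (1.0 - np.cos(2.0 * phi))
               + v3 * (1.0 + np.cos(3.0 * phi)))
    if g is not None:
        dEdphi = 0.5 * (-v1 * np.sin(phi) + 2.0 * v2 * np.sin(2.0 * phi)
                        - 3.0 * v3 * np.sin(3.0 * phi))
        n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), _EPS)
        n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), _EPS)
        F = -(nb2 / n1sq)[:, None] * n1          # dφ/dx_i
        G = (nb2 / n2sq)[:, None] * n2           # dφ/dx_l
        A = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
        B = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
        gi = dEdphi[:, None] * F
        gl = dEdphi[:, None] * G
        gj = dEdphi[:, None] * (-(1.0 + A) * F + B * G)
        gk = dEdphi[:, None] * (A * F - (1.0 + B) * G)
        np.add.at(g, idx[:, 0], gi)
        np.add.at(g, idx[:, 1], gj)
        np.add.at(g, idx[:, 2], gk)
        np.add.at(g, idx[:, 3], gl)
    return float(e.sum())


def buffered_14_7(r, eps, rstar, with_derivative=False):
    """MMFF94 buffered 14-7 van der Waals potential (vectorized).

    E = ε·(1.07R*/(r+0.07R*))⁷·(1.12R*⁷/(r⁷+0.12R*⁷) − 2)
    """
    rho = r + 0.07 * rstar
    t1 = 1.07 * rstar / rho
    r7 = r**7
    rs7 = rstar**7
    den = r7 + 0.12 * rs7
    t2 = 1.12 * rs7 / den - 2.0
    t17 = t1**7
    e = eps * t17 * t2
    if not with_derivative:
        return e
    dt1 = -1.07 * rstar / rho**2
    dt2 = -1.12 * rs7 * 7.0 * r**6 / den**2
    de = eps * (7.0 * t1**6 * dt1 * t2 + t17 * dt2)
    return e, de


def buffered_coulomb(r, qq, dielectric=1.0, delta=_ELE_DELTA,
                     with_derivative=False):
    """Buffered Coulomb term 332.0716·q_iq_j/(D·(r+δ)) (vectorized)."""
    rb = r + delta
    e = _ELE_K * qq / (dielectric * rb)
    if not with_derivative:
        return e
    return e, -_ELE_K * qq / (dielectric * rb**2)


def _nonbonded(X, ps, g):
    if len(ps.nb_idx) == 0:
        return 0.0, 0.0
    d, r = _pair_geometry(X, ps.nb_idx)
    ev, dev = buffered_14_7(r, ps.nb_eps, ps.nb_rstar, with_derivative=True)
    qq = ps.charges[ps.nb_idx[:, 0]] * ps.charges[ps.nb_idx[:, 1]]
    scale = np.where(ps.nb_is14, _SCALE_14, 1.0)
    eq, deq = buffered_coulomb(r, scale * qq, with_derivative=True)
    if g is not None:
        f = ((dev + deq) / r)[:, None] * d
        np.add.at(g, ps.nb_idx[:, 0], f)
        np.add.at(g, ps.nb_idx[:, 1], -f)
    return float(ev.sum()), float(eq.sum())
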