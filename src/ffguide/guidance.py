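"""Energy-guided sampling and post-optimization.

Four samplers: Euler flow matching, diffusion with clean-sample
posterior sampling, and their energy-guided variants.  The guidance
correction subtracts λ·∇E (optionally normalized) from the predicted
clean coordinates X̂₁ *before* the Euler/posterior update — clean-sample
prediction is adopted precisely because it allows the molecular energy
to be evaluated mid-sampling on an actual structure estimate.  With the
normalization off and λ below 2/L (L the local Lipschitz constant of
the energy gradient) the correction is a plain descent step and cannot
increase the energy.

Guidance touches coordinates only; categorical atom/bond state is
carried through unchanged.  All samplers are deterministic given their
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .chem import LigandGraph, PocketStructure
from .cross import CrossTermSpec, total_energy_and_gradient
from .intra import EnergyBreakdown
from .params import MMFFParameterSet, ParameterizationError, parameterize

__all__ = [
    "DenoiserContract", "GuidanceConfig", "DiffusionSchedule", "SamplerState",
    "descent_step", "guidance_step", "flow_sample", "compute_posterior",
    "diffusion_sample", "minimize", "MinimizationResult",
    "estimate_gradient_lipschitz",
]

logger = logging.getLogger(__name__)

_NORM_MODES = ("rms_per_atom", "global_norm", "off")


class DenoiserContract(Protocol):
    """A clean-sample predictor: (X_t, t, pocket) → X̂₁.

    Must return a structure with the same atom count as its input and be
    deterministic given ``(X_t, t)``.
    """

    def __call__(self, xt: LigandGraph, t: float,
                 pocket: PocketStructure | None) -> LigandGraph: ...


@dataclass(frozen=True)
class GuidanceConfig:
    """Energy-guidance hyperparameters.

    ``lam`` scales the gradient correction; with ``rms_per_atom``
    normalization it is the RMS per-atom displacement in Å.  Guidance is
    active for normalized times in ``[guidance_start_t, guidance_end_t]``.
    """

    lam: float = 0.1
    normalize_gradient: str = "rms_per_atom"
    guidance_start_t: float = 0.0
    guidance_end_t: float = 1.0
    skip_on_param_failure: bool = True
    cross_spec: CrossTermSpec = field(default_factory=CrossTermSpec)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.normalize_gradient not in _NORM_MODES:
            raise ValueError(f"normalize_gradient must be one of {_NORM_MODES}")
        if not (0.0 <= self.guidance_start_t <= self.guidance_end_t <= 1.0):
            raise ValueError("need 0 <= guidance_start_t <= guidance_end_t <= 1")

    def active_at(self, t: float) -> bool:
        return self.guidance_start_t <= t <= self.guidance_end_t


@dataclass(frozen=True)
class DiffusionSchedule:
    """Discrete noise schedule over T steps.

    ``alpha_bar[s]`` is the signal fraction after ``s`` forward steps:
    ``alpha_bar[0] = 1`` (clean) and the sequence decreases strictly
    toward the fully noised end.  Normalized time relates to the step
    index through the relabeling τ(t) = round(T·(1 − t)).
    """

    alpha_bar: np.ndarray

    def __post_init__(self) -> None:
        ab = np.asarray(self.alpha_bar, dtype=float)
        object.__setattr__(self, "alpha_bar", ab)
        if ab.ndim != 1 or len(ab) < 2:
            raise ValueError("alpha_bar must be a 1-D sequence of length >= 2")
        if abs(ab[0] - 1.0) > 1e-12:
            raise ValueError("alpha_bar[0] must be 1 (clean end)")
        if np.any(np.diff(ab) >= 0) or np.any(ab <= 0) or np.any(ab[1:] > 1):
            raise ValueError("alpha_bar must be strictly decreasing in (0, 1]")

    @property
    def T(self) -> int:
        return len(self.alpha_bar) - 1

    def tau(self, t: float) -> int:
        """Relabeling τ(t) = round(T·(1 − t))."""
        return int(round(self.T * (1.0 - t)))

    @classmethod
    def cosine(cls, T: int = 100, s: float = 0.008) -> "DiffusionSchedule":
        """Squared-cosine ᾱ schedule (the common default for coordinates)."""
        steps = np.arange(T + 1) / T
        f = np.cos((steps + s) / (1.0 + s) * np.pi / 2.0) ** 2
        ab = np.clip(f / f[0], 1e-8, 1.0)
        ab[0] = 1.0
        return cls(ab)


@dataclass
class SamplerState:
    """Current noisy structure and normalized time t ∈ [0, 1]."""

    structure: LigandGraph
    t: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0):
            raise ValueError("t must lie in [0, 1]")


# ---------------------------------------------------------------------
# guidance correction


def descent_step(coords: np.ndarray, grad: np.ndarray, lam: float,
                 normalize: str = "off") -> np.ndarray:
    """coords − λ·g with optional gradient normalization."""
    g = np.asarray(grad, dtype=float)
    if normalize == "rms_per_atom":
        rms = np.sqrt(np.mean(np.sum(g * g, axis=1)))
        if rms > 1e-12:
            g = g / rms
    elif normalize == "global_norm":
        norm = np.linalg.norm(g)
        if norm > 1e-12:
            g = g / norm
    elif normalize != "off":
        raise ValueError(f"unknown normalization {normalize!r}")
    return np.asarray(coords, dtype=float) - lam * g


def guidance_step(
    xhat1: np.ndarray,
    params: MMFFParameterSet,
    pocket: PocketStructure | None,
    cfg: GuidanceConfig,
) -> np.ndarray:
    """Apply the energy-gradient correction to predicted clean coordinates."""
    _, g = total_energy_and_gradient(xhat1, params, pocket, cfg.cross_spec)
    return descent_step(xhat1, g, cfg.lam, cfg.normalize_gradient)


class _ParamCache:
    """Parameterize each distinct topology once per sampling run."""

    def __init__(self, skip_on_failure: bool):
        self.skip = skip_on_failure
        self._cache: dict[tuple, MMFFParameterSet | None] = {}

    def get(self, structure: LigandGraph) -> MMFFParameterSet | None:
        key = (tuple(structure.elements),
               tuple(structure.formal_charges.tolist()),
               tuple(sorted((min(i, j), max(i, j), o)
                            for i, j, o in structure.bonds)))
        if key not in self._cache:
            try:
                self._cache[key] = parameterize(structure)
            except ParameterizationError as exc:
                if not self.skip:
                    raise
                logger.warning("guidance skipped: %s", exc)
                self._cache[key] = None
        return self._cache[key]


def _guided_xhat(xhat: LigandGraph, t: float, pocket, cfg,
                 cache: _ParamCache) -> np.ndarray:
    coords = xhat.coords
    if cfg is None or not cfg.active_at(t):
        return coords
    params = cache.get(xhat)
    if params is None:
        return coords
    return guidance_step(coords, params, pocket, cfg)


# ---------------------------------------------------------------------
# samplers


def _check_denoiser_output(xhat: LigandGraph, n: int) -> None:
    if xhat.n_atoms != n:
        raise ValueError(
            f"denoiser returned {xhat.n_atoms} atoms, expected {n}")


def flow_sample(
    x0: LigandGraph,
    denoiser: DenoiserContract,
    pocket: PocketStructure | None = None,
    steps: int = 100,
    cfg: GuidanceConfig | None = None,
) -> LigandGraph:
    """Euler flow-matching sampler, optionally energy-guided.

    Integrates the clean-sample vector field u = (X̂₁ − X_t)/(1 − t)
    from t = 0 to 1 with uniform steps.  When ``cfg`` is given, X̂₁ is
    corrected by :func:`guidance_step` before each update.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    cache = _ParamCache(cfg.skip_on_param_failure if cfg else True)
    x = x0.with_coords(x0.coords)
    dt = 1.0 / steps
    for s in range(steps):
        t = s * dt
        xhat = denoiser(x, t, pocket)
        _check_denoiser_output(xhat, x0.n_atoms)
        coords_hat = _guided_xhat(xhat, t, pocket, cfg, cache)
        if s == steps - 1:
            # last step: dt == 1 - t exactly, so the update lands on X̂₁
            x = x.with_coords(coords_hat)
        else:
            u = (coords_hat - x.coords) / max(1.0 - t, 1e-6)
            x = x.with_coords(x.coords + dt * u)
    return x


def posterior_coefficients(step_index: int,
                           schedule: DiffusionSchedule) -> tuple[float, float]:
    """Clean-sample coefficient c₀ and posterior variance for one step.

    c₀ = √ᾱ_{s−1}·β_s/(1 − ᾱ_s) (clipped to [0, 1]) and
    β̃_s = (1 − ᾱ_{s−1})/(1 − ᾱ_s)·β_s, with β_s = 1 − ᾱ_s/ᾱ_{s−1}.
    At the clean end (s = 1): c₀ = 1 and β̃₁ = 0.
    """
    ab = schedule.alpha_bar
    s = step_index
    if not (1 <= s <= schedule.T):
        raise ValueError(f"step_index {s} outside [1, {schedule.T}]")
    beta_s = 1.0 - ab[s] / ab[s - 1]
    c0 = float(np.clip(np.sqrt(ab[s - 1]) * beta_s / (1.0 - ab[s]), 0.0, 1.0))
    var = float((1.0 - ab[s - 1]) / (1.0 - ab[s]) * beta_s)
    return c0, var


def compute_posterior(
    xhat1: np.ndarray,
    xt: np.ndarray,
    step_index: int,
    schedule: DiffusionSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the previous diffusion state given the clean estimate.

    The mean is the convex combination c₀·X̂₁ + (1 − c₀)·X_t with the
    clean-sample coefficient of the forward-process Gaussian posterior;
    the variance is the standard posterior variance (see
    :func:`posterior_coefficients`).  The final step (s = 1) is
    deterministic.
    """
    c0, var = posterior_coefficients(step_index, schedule)
    mean = c0 * np.asarray(xhat1, float) + (1.0 - c0) * np.asarray(xt, float)
    if step_index == 1 or var <= 0.0:
        return mean
    return mean + np.sqrt(var) * rng.standard_normal(mean.shape)


def diffusion_sample(
    xT: LigandGraph,
    denoiser: DenoiserContract,
    pocket: PocketStructure | None = None,
    schedule: DiffusionSchedule | None = None,
    cfg: GuidanceConfig | None = None,
    seed: int = 0,
) -> LigandGraph:
    """Ancestral diffusion sampler with clean-sample prediction.

    Iterates denoise → (optional guidance on X̂₁) → posterior sample
    from the fully noised end (step index T) down to the clean end.
    """
    if schedule is None:
        schedule = DiffusionSchedule.cosine()
    rng = np.random.default_rng(seed)
    cache = _ParamCache(cfg.skip_on_param_failure if cfg else True)
    x = xT.with_coords(xT.coords)
    for s in range(schedule.T, 0, -1):
        t = 1.0 - s / schedule.T
        xhat = denoiser(x, t, pocket)
        _check_denoiser_output(xhat, xT.n_atoms)
        coords_hat = _guided_xhat(xhat, t, pocket, cfg, cache)
        x = x.with_coords(
            compute_posterior(coords_hat, x.coords, s, schedule, rng))
    return x


# ---------------------------------------------------------------------
# post-optimization


@dataclass
class MinimizationResult:
    """Outcome of :func:`minimize`; unpacks as ``(ligand, breakdown)``."""

    ligand: LigandGraph
    breakdown: EnergyBreakdown
    energy_trace: np.ndarray
    n_iter: int
    converged: bool

    def __iter__(self):
        return iter((self.ligand, self.breakdown))


def minimize(
    ligand: LigandGraph,
    pocket: PocketStructure | None = None,
    max_iters: int = 500,
    tol_grad: float = 1e-4,
    spec: CrossTermSpec = CrossTermSpec(),
) -> MinimizationResult:
    """Protein-conditioned MMFF94 minimization of ligand coordinates.

    BFGS with a Wolfe line search over the total energy (the same
    family of quasi-Newton descent the reference toolkit uses, so both
    follow comparable paths from identical starts); the pocket (if any)
    stays rigid.  Terminates when the gradient max-norm falls below
    ``tol_grad`` (kcal/mol/Å) or after ``max_iters`` accepted
    iterations.  The returned energy never exceeds the starting energy.
    """
    from scipy.optimize import minimize as scipy_minimize

    params = parameterize(ligand)
    n = params.n_atoms
    if ligand.n_atoms != n:
        raise ParameterizationError(
            "minimize requires explicit hydrogens on the input graph")
    x0 = ligand.coords.ravel().copy()

    def fun(x):
        br, g = total_energy_and_gradient(x.reshape(n, 3), params, pocket, spec)
        return br.total, g.ravel()

    trace = [fun(x0)[0]]
    best = {"x": x0.copy(), "e": trace[0]}

    def cb(xk):
        e = fun(xk)[0]
        trace.append(e)
        if e < best["e"]:
            best["x"], best["e"] = xk.copy(), e

    res = scipy_minimize(
        fun, x0, jac=True, method="BFGS", callback=cb,
        options={"maxiter": max_iters, "gtol": tol_grad})
    xf = res.x if fun(res.x)[0] <= best["e"] else best["x"]
    coords = xf.reshape(n, 3)
    br, g = total_energy_and_gradient(coords, params, pocket, spec)
    converged = bool(np.abs(g).max() <= tol_grad) or res.success
    return MinimizationResult(
        ligand=ligand.with_coords(coords),
        breakdown=br,
        energy_trace=np.array(trace),
        n_iter=int(res.nit),
        converged=converged,
    )


# ---------------------------------------------------------------------
# diagnostics


def estimate_gradient_lipschitz(
    coords: np.ndarray,
    grad_fn: Callable[[np.ndarray], np.ndarray],
    n_iter: int = 25,
    fd_eps: float = 1e-4,
    seed: int = 0,
) -> float:
    """Local Lipschitz constant of a gradient field near ``coords``.

    Power iteration on the Hessian through central finite differences of
    ``grad_fn``; returns the dominant |eigenvalue|, which bounds the
    gradient's local rate of change.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(coords, dtype=float)
    v = rng.standard_normal(x.shape)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        hv = (grad_fn(x + fd_eps * v) - grad_fn(x - fd_eps * v)) / (2 * fd_eps)
        lam = float(np.linalg.norm(hv))
        if lam < 1e-12:
            break
        v = hv / lam
    return lam
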