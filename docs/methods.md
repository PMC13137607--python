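# Methods

## Scope and model

`ffguide` implements a training-free, physics-based guidance layer for
3D molecular generators.  Its core is a pocket-conditioned molecular
mechanics energy

    E(X, Y) = MMFF94(X) + E_vdW(X, Y) + E_Q(X, Y),

where `X` is a ligand with coordinates, atom types, formal charges and
typed bonds, and `Y` is a rigid set of protein-pocket atoms with
partial charges and nonbonded parameters.  `MMFF94(X)` is the full
intramolecular Merck Molecular Force Field: cubic bond stretch,
cubic-corrected angle bend with a linear special case, stretch–bend
coupling, Wilson-angle out-of-plane bend, a three-term torsion cosine
series, the buffered 14-7 van der Waals potential, and the buffered
Coulomb term with 0.75 scaling of 1-4 interactions.  The two nonbonded
terms are extended across the ligand–pocket interface over *all*
ligand-atom × pocket-atom pairs, with no cutoff, no exclusions and no
interface scaling — there are no covalent paths across the interface.

The energy is differentiable: every term has a hand-derived analytic
gradient, implemented as vectorized NumPy kernels over a neutral
per-molecule parameter table (`MMFFParameterSet`).  Gradients are exact
derivatives of the implemented energy; tests verify them against
central finite differences (step 1e-5 Å, relative error < 1e-5) and
verify the energy itself against RDKit's MMFF94 single point
(agreement to ~1e-12 kcal/mol, far inside the 1e-4 contract).

## Parameter acquisition

Atom typing and parameter lookup are not reimplemented: RDKit assigns
MMFF94 atom types, charges and term parameters, and the adapter
serializes them into `MMFFParameterSet`.  The energy/gradient kernels
are pure numerics over that table, so they are unit-testable with
hand-built parameter sets and independent of the toolkit at evaluation
time.  Term enumeration mirrors RDKit exactly (including torsions
inside three-membered rings being skipped via missing parameters, and
the three Wilson angles per tricoordinate centre).  Molecules with
implicit hydrogens are protonated deterministically before typing;
MMFF94 requires explicit hydrogens.

Electrostatic conventions follow the reference implementation:
dielectric D = 1, distance exponent 1, buffering δ = 0.05 Å, constant
332.0716 kcal·Å/(mol·e²), 1-4 scale 0.75.  The MMFF94 variant (not
MMFF94s) is used throughout.

## Cross-term pair parameters

For intramolecular pairs the exact RDKit pair parameters (which
include donor–acceptor scaling) are stored per pair.  Across the
interface only per-atom diagonal values (ε_i, R*_i) are available, so
pair parameters are combined with the MMFF94 arithmetic rule with the
non-additive expansion,

    R*_ij = ½(R*_i + R*_j)(1 + 0.2(1 − exp(−12 γ²))),
    γ = (R*_i − R*_j)/(R*_i + R*_j),

and a well depth ε_ij = √(ε_i ε_j)·(R*_i R*_j)³/R*_ij⁶, which
preserves the MMFF94 ε ∝ R*⁻⁶ structure and is exact for identical
atoms (for unlike pairs it replaces the Slater–Kirkwood denominator by
its geometric mean, a ≤ few-percent approximation).  Pocket atoms get
diagonal parameters from MMFF94 typing of the perceived protein graph
when RDKit can perceive one, else from a frozen per-element table of
representative MMFF94 diagonal values.  Pocket charges are inputs
(file column, sidecar CSV, or a Gasteiger fallback) and are never
recomputed during a run.

## Samplers and the guidance correction

Both samplers predict the clean sample X̂₁ at every step, which is what
makes mid-sampling energy evaluation possible:

* **Flow matching** — Euler integration of u = (X̂₁ − X_t)/(1 − t)
  from t = 0 to 1 with uniform steps.  The last step has dt = 1 − t
  exactly, so it is implemented as a direct assignment to X̂₁ (this
  also makes the perfect-denoiser identity exact to the bit).
* **Diffusion** — ancestral sampling over a discrete ᾱ schedule
  (default: squared-cosine, T = 100; both configurable) with the
  relabeling τ(t) = round(T(1 − t)) connecting step indices to the
  flow-style normalized time.

**Posterior.**  Given the clean estimate X̂₁ and the current state X_s,
the previous state is drawn with mean c₀·X̂₁ + (1 − c₀)·X_s and the
standard forward-posterior variance β̃_s = (1 − ᾱ_{s−1})(1 − ᾱ_s/ᾱ_{s−1})/(1 − ᾱ_s).
The clean-sample coefficient is the forward-posterior one,
c₀ = √ᾱ_{s−1}·β_s/(1 − ᾱ_s); the X_s coefficient is taken as 1 − c₀ so
the mean is an exact convex combination.  (The textbook pair of
coefficients sums to approximately but not exactly one; the convex
form keeps X̂₁ = X_s a fixed point of the mean and makes the final
step, where c₀ = 1 and β̃ = 0, exactly deterministic.)  This was a
genuinely open design point and is the package's own choice.

**Guidance.**  The correction X̂₁ ← X̂₁ − λ·g is applied to the
predicted clean coordinates *before* the Euler/posterior update, where
g = ∇E(X̂₁, Y) optionally normalized.  Default normalization divides g
by its per-molecule RMS atom norm, so λ is the RMS per-atom
displacement in Å (default λ = 0.1; it must be set explicitly for
reproducible comparisons).  Guidance touches coordinates only;
categorical atom/bond state passes through unchanged.  Guidance can be
restricted to a time window [guidance_start_t, guidance_end_t]
(default: every step).  If parameterization of an intermediate
prediction fails, the default is to skip the correction for that step
with a log message, so the guided sampler degrades gracefully to the
base algorithm; set `skip_on_param_failure=False` to raise instead.

With normalization off and λ < 2/L — L the local Lipschitz constant of
∇E — the correction is a plain gradient-descent step and cannot
increase the energy.  `estimate_gradient_lipschitz` estimates L by
power iteration on finite-difference Hessian-vector products; tests
confirm descent at λ = 1/L and use λ = 4/L as a negative control.

## Post-optimization and metrics

`minimize` performs pocket-conditioned MMFF94 minimization of the
ligand with a rigid pocket, using dense BFGS with a Wolfe line search —
the same quasi-Newton family as the reference toolkit's minimizer, so
both follow comparable descent paths from identical starts (observed
endpoint agreement ~1e-12 kcal/mol on perturbed fixtures).  The energy
trace over accepted iterates is returned and is non-increasing; the
result never exceeds the starting energy.

Strain energy is (E_generated − E_optimized)/n_heavy in kcal/mol per
heavy atom, both sides intramolecular MMFF94 by default ("the pose
versus its own force-field minimum"); passing a pocket switches both
sides to the pocket-conditioned total (conditional strain).  Validity
is operational: the record parses, sanitizes, and initializes an
MMFF94 parameter set.

## Synthetic fixtures and what they show

No external data is used.  `make_fixture_set` embeds a packaged list
of ~50 drug-like SMILES (ETKDG, seeded) with explicit hydrogens;
`make_toy_pocket` builds small charged-sphere, ring and distant-shell
environments; `make_toy_denoiser` provides clean-sample predictors:
`perfect` (returns the target), `noisy_target` (target plus noise that
shrinks as t → 1), and `strained_target` (a fixed conformer displaced
by 0.25 Å Gaussian noise per coordinate — deliberately strained).

The paired guided/unguided experiments fix all seeds per pair so the
two arms differ only in λ.  Problem sizes: 100 molecules for the
energy-oracle comparison, 10 for finite-difference and minimizer
checks, 100 pairs per sampler (flow with 15 Euler steps, diffusion
with T = 20) for the effect-direction experiments — sizes chosen so a
desk machine reproduces everything in a couple of minutes.  With the
deliberately simple constant `strained_target` denoiser the flow and
diffusion endpoints coincide (both collapse to the final clean-sample
estimate), so the guided improvement there measures exactly one
descent step at the clean end; the `noisy_target` denoiser exercises
the full trajectories instead.  These toys demonstrate the mechanism
and the direction of the effect — lower final energy and lower strain
under guidance — not the magnitudes attainable with a trained
generative model on real pockets.

## Numerical choices and limitations

* Degenerate geometries are guarded: interatomic distances are clamped
  at 1e-6 Å inside square roots, sines of angles at 1e-8, the final
  flow-step denominator at 1e-6; energies and gradients stay finite
  for coincident atoms and collinear angles.
* Linear angle centres are detected by θ₀ = 180°, which matches the
  MMFF94 parameter tables.
* The Lipschitz estimator uses 25 power iterations with 1e-4 Å
  displacements; it estimates the *local* curvature, so the descent
  guarantee is local too.
* Protein perception for Gasteiger/typing fallback relies on RDKit's
  PDB reader; exotic residues fall back to the element table and, for
  charges, to zeros with a warning.
* Protonation states are taken as given; there is no PrepWizard-style
  preparation, no mmCIF support, and no protein flexibility.
* Docking scores, PoseBusters checks, hydrogen-bond counting and
  trained generative backbones are out of scope; the toy denoisers are
  stand-ins that satisfy the same interface contract.
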