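"""Samplers, the guidance correction, posterior sampling, minimization."""

import numpy as np
import pytest

import ffguide as fg
from ffguide.guidance import DiffusionSchedule, descent_step


@pytest.fixture(scope="module")
def target(fixture_molecules):
    return min(fixture_molecules, key=lambda m: m.n_atoms)


@pytest.fixture(scope="module")
def target_params(target):
    return fg.parameterize(target)


def _noise_start(target, seed):
    rng = np.random.default_rng(seed)
    return target.with_coords(rng.standard_normal(target.coords.shape))


class TestDescentStep:
    def test_quadratic_surrogate_closed_form(self):
        # E = ||x||², ∇E = 2x, L = 2; λ = 0.25 < 2/L gives a strict
        # contraction: ||x'||² = (1 − 2λ)²||x||²
        rng = np.random.default_rng(0)
        x = rng.standard_normal((7, 3))
        out = descent_step(x, 2 * x, lam=0.25, normalize="off")
        assert np.allclose(out, 0.5 * x)
        assert np.sum(out**2) == pytest.approx(0.25 * np.sum(x**2))

    def test_lambda_zero_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 3))
        g = rng.standard_normal((5, 3))
        for mode in ("off", "rms_per_atom", "global_norm"):
            assert np.array_equal(descent_step(x, g, 0.0, mode), x)

    def test_rms_normalization_sets_step_length(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 3))
        g = rng.standard_normal((6, 3))
        out = descent_step(x, g, lam=0.1, normalize="rms_per_atom")
        disp = out - x
        rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        assert rms == pytest.approx(0.1)


class TestGuidanceStep:
    def test_lowers_energy_of_strained_geometry(self, target, target_params):
        rng = np.random.default_rng(3)
        strained = target.coords + 0.2 * rng.standard_normal(
            target.coords.shape)
        e0 = fg.energy_intra(strained, target_params).total
        cfg = fg.GuidanceConfig(lam=0.01, normalize_gradient="rms_per_atom")
        out = fg.guidance_step(strained, target_params, None, cfg)
        assert fg.energy_intra(out, target_params).total < e0

    def test_descent_guarantee_below_two_over_l(self, target, target_params):
        rng = np.random.default_rng(4)
        coords = target.coords + 0.05 * rng.standard_normal(
            target.coords.shape)
        grad_fn = lambda x: fg.gradient_intra(x, target_params)
        L = fg.estimate_gradient_lipschitz(coords, grad_fn, seed=0)
        e0 = fg.energy_intra(coords, target_params).total
        cfg = fg.GuidanceConfig(lam=1.0 / L, normalize_gradient="off")
        out = fg.guidance_step(coords, target_params, None, cfg)
        assert fg.energy_intra(out, target_params).total < e0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            fg.GuidanceConfig(lam=-1.0)
        with pytest.raises(ValueError):
            fg.GuidanceConfig(normalize_gradient="bogus")
        with pytest.raises(ValueError):
            fg.GuidanceConfig(guidance_start_t=0.9, guidance_end_t=0.1)


class TestFlowSampler:
    def test_perfect_denoiser_recovers_target(self, target):
        den = fg.make_toy_denoiser("perfect", target)
        for steps in (1, 3, 17):
            out = fg.flow_sample(_noise_start(target, 0), den, steps=steps)
            assert np.abs(out.coords - target.coords).max() < 1e-10

    def test_single_step_returns_denoiser_output(self, target):
        den = fg.make_toy_denoiser("noisy_target", target, seed=5)
        x0 = _noise_start(target, 1)
        out = fg.flow_sample(x0, den, steps=1)
        expected = den(x0, 0.0, None).coords
        assert np.array_equal(out.coords, expected)

    def test_lambda_zero_matches_unguided_bitwise(self, target):
        den = fg.make_toy_denoiser("strained_target", target, seed=6)
        for seed in range(5):
            x0 = _noise_start(target, seed)
            base = fg.flow_sample(x0, den, steps=8)
            guided = fg.flow_sample(
                x0, den, steps=8,
                cfg=fg.GuidanceConfig(lam=0.0, normalize_gradient="off"))
            assert np.array_equal(base.coords, guided.coords)

    def test_guidance_lowers_final_energy_in_paired_runs(self, target,
                                                         target_params):
        from scipy import stats

        diffs = []
        for seed in range(20):
            den = fg.make_toy_denoiser("strained_target", target, seed=seed)
            x0 = _noise_start(target, seed)
            un = fg.flow_sample(x0, den, steps=15)
            gd = fg.flow_sample(x0, den, steps=15,
                                cfg=fg.GuidanceConfig(lam=0.1))
            e_un = fg.energy_intra(un.coords, target_params).total
            e_gd = fg.energy_intra(gd.coords, target_params).total
            diffs.append(e_un - e_gd)
        assert np.mean(diffs) > 0
        p = stats.ttest_1samp(diffs, 0.0, alternative="greater").pvalue
        assert p < 0.01

    def test_denoiser_atom_count_violation_raises(self, target):
        def bad(xt, t, pocket=None):
            return fg.LigandGraph(np.zeros((2, 3)), ["C", "C"], np.zeros(2),
                                  [(0, 1, "single")])

        with pytest.raises(ValueError, match="atoms"):
            fg.flow_sample(_noise_start(target, 0), bad, steps=2)


class TestPosterior:
    def _schedule(self):
        return DiffusionSchedule.cosine(T=12)

    def test_final_step_is_deterministic_mean(self):
        sch = self._schedule()
        rng = np.random.default_rng(0)
        xhat = rng.standard_normal((4, 3))
        xt = rng.standard_normal((4, 3))
        a = fg.compute_posterior(xhat, xt, 1, sch, np.random.default_rng(1))
        b = fg.compute_posterior(xhat, xt, 1, sch, np.random.default_rng(2))
        assert np.array_equal(a, b)
        assert np.allclose(a, xhat)  # c0 = 1 at the clean end

    def test_identical_inputs_give_identity_mean(self):
        # the mean is a convex combination, so xhat1 == xt is its own mean
        from ffguide.guidance import posterior_coefficients

        sch = self._schedule()
        x = np.random.default_rng(3).standard_normal((5, 3))
        for s in range(1, sch.T + 1):
            c0, var = posterior_coefficients(s, sch)
            mean = c0 * x + (1 - c0) * x
            assert np.allclose(mean, x)
        assert np.allclose(
            fg.compute_posterior(x, x, 1, sch, np.random.default_rng(0)), x)

    def test_coefficients_match_scalar_recomputation(self):
        # independent scalar recomputation straight from the ᾱ sequence
        from ffguide.guidance import posterior_coefficients

        sch = self._schedule()
        ab = sch.alpha_bar
        for s in range(1, sch.T + 1):
            beta = 1.0 - ab[s] / ab[s - 1]
            c0_ref = min(1.0, float(np.sqrt(ab[s - 1]) * beta / (1 - ab[s])))
            var_ref = float((1 - ab[s - 1]) / (1 - ab[s]) * beta)
            c0, var = posterior_coefficients(s, sch)
            assert c0 == pytest.approx(c0_ref, abs=1e-14)
            assert var == pytest.approx(var_ref, abs=1e-14)
            assert 0.0 <= c0 <= 1.0 and var >= 0.0
        assert posterior_coefficients(1, sch) == (1.0, 0.0)

    def test_out_of_range_step_raises(self):
        sch = self._schedule()
        x = np.zeros((2, 3))
        for s in (0, sch.T + 1):
            with pytest.raises(ValueError):
                fg.compute_posterior(x, x, s, sch, np.random.default_rng(0))

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            DiffusionSchedule(np.array([0.9, 0.5]))  # must start at 1
        with pytest.raises(ValueError):
            DiffusionSchedule(np.array([1.0, 0.5, 0.6]))  # not decreasing
        sch = DiffusionSchedule.cosine(T=10)
        assert sch.tau(1.0) == 0 and sch.tau(0.0) == 10


class TestDiffusionSampler:
    def test_perfect_denoiser_reaches_target(self, target):
        den = fg.make_toy_denoiser("perfect", target)
        sch = DiffusionSchedule.cosine(T=10)
        out = fg.diffusion_sample(_noise_start(target, 0), den, schedule=sch,
                                  seed=7)
        assert np.abs(out.coords - target.coords).max() < 1e-6

    def test_same_seed_same_trajectory(self, target):
        den = fg.make_toy_denoiser("noisy_target", target, seed=8)
        sch = DiffusionSchedule.cosine(T=10)
        x0 = _noise_start(target, 2)
        a = fg.diffusion_sample(x0, den, schedule=sch, seed=11)
        b = fg.diffusion_sample(x0, den, schedule=sch, seed=11)
        assert np.array_equal(a.coords, b.coords)

    def test_lambda_zero_matches_unguided_bitwise(self, target):
        den = fg.make_toy_denoiser("strained_target", target, seed=9)
        sch = DiffusionSchedule.cosine(T=8)
        for seed in range(5):
            x0 = _noise_start(target, seed)
            base = fg.diffusion_sample(x0, den, schedule=sch, seed=seed)
            guided = fg.diffusion_sample(
                x0, den, schedule=sch, seed=seed,
                cfg=fg.GuidanceConfig(lam=0.0, normalize_gradient="off"))
            assert np.array_equal(base.coords, guided.coords)

    def test_guidance_lowers_final_energy(self, target, target_params):
        den = fg.make_toy_denoiser("strained_target", target, seed=10)
        sch = DiffusionSchedule.cosine(T=10)
        x0 = _noise_start(target, 3)
        un = fg.diffusion_sample(x0, den, schedule=sch, seed=4)
        gd = fg.diffusion_sample(x0, den, schedule=sch, seed=4,
                                 cfg=fg.GuidanceConfig(lam=0.1))
        assert (fg.energy_intra(gd.coords, target_params).total
                < fg.energy_intra(un.coords, target_params).total)


class TestMinimize:
    def test_converged_start_is_fixed_point(self, target):
        first = fg.minimize(target, max_iters=800, tol_grad=1e-5)
        again = fg.minimize(first.ligand, max_iters=800, tol_grad=1e-5)
        assert again.n_iter <= 1
        assert np.abs(again.ligand.coords - first.ligand.coords).max() < 1e-3

    def test_monotone_energy_trace(self, fixture_molecules):
        for mol in fixture_molecules[:3]:
            res = fg.minimize(mol, max_iters=300)
            assert np.all(np.diff(res.energy_trace) <= 1e-6)
            assert res.breakdown.total <= res.energy_trace[0]

    def test_endpoint_matches_reference_minimizer(self, target):
        from rdkit.Chem import AllChem

        rng = np.random.default_rng(12)
        start = target.with_coords(
            target.coords + 0.3 * rng.standard_normal(target.coords.shape))
        res = fg.minimize(start, max_iters=2000, tol_grad=1e-5)
        rd = start.to_rdkit()
        ff = AllChem.MMFFGetMoleculeForceField(
            rd, AllChem.MMFFGetMoleculeProperties(rd))
        ff.Minimize(maxIts=5000, forceTol=1e-6)
        assert res.breakdown.total <= ff.CalcEnergy() + 0.5

    def test_pocket_conditioned_descent(self, target, toy_pocket):
        res = fg.minimize(target, pocket=toy_pocket, max_iters=150)
        assert res.breakdown.total <= res.energy_trace[0]
        assert res.breakdown.cross_vdw != 0.0
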