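"""Generative pipeline: truth assignment, sampling ops and composition."""

import numpy as np
import pytest
from scipy import stats

from cspower import (
    DirichletParams,
    InvalidInputError,
    ScenarioConfig,
    assign_de_truth,
    convolve_and_count,
    sample_cts_profiles,
    sample_proportions,
    simulate_dataset,
)
from cspower.params import GammaProfileParams, build_synthetic_paramset
from cspower.simulator import enforce_sign_floor


def _flat_gamma(G, K, log_mean, log_var):
    shape = np.full((G, K, 2), log_mean**2 / log_var)
    rate = np.full((G, K, 2), log_mean / log_var)
    return GammaProfileParams(shape=shape, rate=rate)


class TestAssignDETruth:
    def test_rounding_contract(self):
        t = assign_de_truth(10, 3, 0.2, 1.0, seed=0)
        assert t.is_de.sum() == 2

    def test_null_effect_gives_zero_lfc(self):
        t = assign_de_truth(100, 3, 0.3, 0.0, seed=1)
        assert np.all(t.lfc == 0)
        assert t.is_de.sum() == 30  # flagged, but no effect

    def test_target_celltypes_uniform(self):
        t = assign_de_truth(9_000, 3, 0.1, 0.5, seed=2)
        counts = np.bincount(t.target_celltype[t.is_de], minlength=3)
        lo = stats.binom.ppf(0.0005, 900, 1 / 3)
        hi = stats.binom.ppf(0.9995, 900, 1 / 3)
        assert np.all((counts >= lo) & (counts <= hi))

    def test_signs_equiprobable(self):
        t = assign_de_truth(10_000, 4, 0.5, 1.0, seed=3)
        n_up = (t.lfc > 0).sum()
        assert stats.binom.ppf(0.0005, 5000, 0.5) <= n_up
        assert n_up <= stats.binom.ppf(0.9995, 5000, 0.5)

    def test_deterministic(self):
        a = assign_de_truth(200, 3, 0.1, 0.5, seed=7)
        b = assign_de_truth(200, 3, 0.1, 0.5, seed=7)
        assert np.array_equal(a.lfc, b.lfc)
        assert np.array_equal(a.target_celltype, b.target_celltype)

    def test_invalid_de_fraction(self):
        with pytest.raises(InvalidInputError):
            assign_de_truth(10, 3, 1.0, 0.5, seed=0)

    def test_sign_floor_flips_infeasible_downregulation(self):
        gamma = _flat_gamma(10, 2, log_mean=0.5, log_var=0.01)
        t = assign_de_truth(10, 2, 0.5, 1.0, seed=11)
        fixed = enforce_sign_floor(t, gamma)
        # 0.5 - 1.0 <= 0.1, so every down effect must have been flipped up
        assert np.all(fixed.lfc[fixed.is_de] == 1.0)


class TestSampleProportions:
    def test_mean_converges_to_dirichlet_mean(self):
        d = DirichletParams(alpha=np.tile([[1.0], [1.0]], 2))
        P = sample_proportions(d, 10_000, "control", seed=4)
        assert np.all(np.abs(P.mean(0) - 0.5) < 0.02)

    def test_concentration_reduces_variance(self):
        lo = DirichletParams(alpha=np.tile([[1.0], [1.0], [1.0]], 2))
        hi = DirichletParams(alpha=np.tile([[100.0], [100.0], [100.0]], 2))
        v_lo = sample_proportions(lo, 10_000, 0, seed=5).var(0)
        v_hi = sample_proportions(hi, 10_000, 0, seed=5).var(0)
        assert np.all(v_hi < v_lo)

    def test_single_row_on_simplex(self):
        d = DirichletParams(alpha=np.tile([[2.0], [3.0]], 2))
        P = sample_proportions(d, 1, "case", seed=6)
        assert P.shape == (1, 2)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)


class TestSampleCtsProfiles:
    def test_null_groups_agree(self):
        gamma = _flat_gamma(5, 2, log_mean=5.0, log_var=0.05)
        t = assign_de_truth(5, 2, 0.2, 0.0, seed=8)
        a = sample_cts_profiles(gamma, t, "control", 5_000, seed=9).mean(axis=2)
        b = sample_cts_profiles(gamma, t, "case", 5_000, seed=10).mean(axis=2)
        assert np.allclose(a, b, rtol=0.02)

    def test_lfc_shifts_target_celltype_only(self):
        # low dispersion -> expression ratio for lfc=1 is ~2**1 = 2
        gamma = _flat_gamma(1, 3, log_mean=8.0, log_var=0.01)
        t_up = assign_de_truth(1, 3, 0.5, 0.0, seed=0)  # template
        import dataclasses
        truth = dataclasses.replace(
            t_up, is_de=np.array([True]), target_celltype=np.array([1]),
            lfc=np.array([1.0]))
        ctrl = sample_cts_profiles(gamma, truth, "control", 5_000, seed=12)
        case = sample_cts_profiles(gamma, truth, "case", 5_000, seed=13)
        ratio = case.mean(axis=2) / ctrl.mean(axis=2)
        assert ratio[0, 1] == pytest.approx(2.0, rel=0.05)
        assert ratio[0, 0] == pytest.approx(1.0, rel=0.05)
        assert ratio[0, 2] == pytest.approx(1.0, rel=0.05)

    def test_large_shape_collapses_variance(self):
        tight = _flat_gamma(1, 1, log_mean=4.0, log_var=1e-6)
        t = assign_de_truth(1, 2, 0.5, 0.0, seed=0)
        import dataclasses
        t = dataclasses.replace(t, is_de=t.is_de[:1],
                                target_celltype=t.target_celltype[:1],
                                lfc=t.lfc[:1])
        draws = sample_cts_profiles(
            GammaProfileParams(shape=tight.shape[:, :1], rate=tight.rate[:, :1]),
            t, "control", 2_000, seed=14)
        assert draws.std() / draws.mean() < 0.01


class TestConvolveAndCount:
    def test_weighted_average_rate(self):
        cts = np.array([[[10.0], [30.0]]])  # G=1, K=2, n=1
        P = np.array([[0.5, 0.5]])
        counts = np.array([
            convolve_and_count(cts, P, np.array([1.0]), seed=s)[0, 0]
            for s in range(20_000)
        ])
        assert counts.mean() == pytest.approx(20.0, rel=0.02)
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.05)

    def test_total_count_matches_poisson_additivity(self, rng):
        """Total counts across replicate draws sit within 3 MC standard
        errors of the latent rate total."""
        G, K, n = 50, 3, 8
        cts = rng.gamma(5.0, 20.0, size=(G, K, n))
        P = rng.dirichlet(np.ones(K), size=n)
        depth = rng.uniform(0.5, 1.5, size=n)
        lam_total = float(
            (depth[None, :] * np.einsum("gki,ik->gi", cts, P)).sum())
        reps = 50
        totals = [convolve_and_count(cts, P, depth, seed=s).sum()
                  for s in range(reps)]
        se = np.sqrt(lam_total / reps)
        assert abs(np.mean(totals) - lam_total) < 3 * se

    def test_negative_expression_rejected(self):
        with pytest.raises(InvalidInputError):
            convolve_and_count(np.full((1, 1, 1), -1.0), np.array([[1.0]]),
                               np.array([1.0]), seed=0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            convolve_and_count(np.ones((2, 2, 3)), np.ones((3, 3)) / 3,
                               np.ones(3), seed=0)


class TestSimulateDataset:
    def test_seed_determinism(self, small_params):
        sc = ScenarioConfig(n_per_group=10, effect_size=0.5, n_genes=400, seed=77)
        a = simulate_dataset(small_params, sc)
        b = simulate_dataset(small_params, sc)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.proportions, b.proportions)
        assert np.array_equal(a.truth.lfc, b.truth.lfc)

    def test_reference_scenario_shape(self, small_params):
        sc = ScenarioConfig(n_per_group=50, effect_size=0.5, n_genes=400, seed=78)
        ds = simulate_dataset(small_params, sc)
        assert ds.n_samples == 100
        assert ds.truth.is_de.sum() == 20  # 5% of 400
        assert np.allclose(ds.proportions.sum(1), 1.0, atol=1e-9)
        assert np.issubdtype(ds.counts.dtype, np.integer)
        assert np.all(ds.counts >= 0)

    def test_expected_counts_conservation(self, small_params):
        """E[counts] = depth x (proportion-weighted latent expression):
        the realized grand total must sit within Poisson error of the
        latent rate total, reconstructed from an identically seeded run."""
        from cspower.simulator import (_child_seeds, enforce_sign_floor,
                                       sample_cts_profiles, sample_proportions)
        from cspower import assign_de_truth
        sc = ScenarioConfig(n_per_group=30, effect_size=0.0, n_genes=400, seed=79)
        ds = simulate_dataset(small_params, sc)
        (s_truth, s_p0, s_p1, s_c0, s_c1, s_depth, _) = _child_seeds(79, 7)
        truth = enforce_sign_floor(
            assign_de_truth(400, 3, 0.05, 0.0, s_truth), small_params.gamma)
        cts = np.concatenate([
            sample_cts_profiles(small_params.gamma, truth, "control", 30, s_c0),
            sample_cts_profiles(small_params.gamma, truth, "case", 30, s_c1),
        ], axis=2)
        lam = ds.depth[None, :] * np.einsum("gki,ik->gi", cts, ds.proportions)
        assert abs(ds.counts.sum() - lam.sum()) < 3 * np.sqrt(lam.sum())

    def test_null_symmetry_across_replicates(self):
        """With effect size 0, case-control differences are centered at 0.

        Genes within one dataset share the same composition and depth
        draws, so their differences are correlated; symmetry is therefore
        asserted on the replicate level: the per-replicate fraction of
        genes with a positive library-normalized difference averages 0.5.
        """
        ps = build_synthetic_paramset(500, 3, (4.5, 9.0, 16.5), seed=55)
        fracs = []
        for rep in range(30):
            sc = ScenarioConfig(n_per_group=50, effect_size=0.0, n_genes=500,
                                seed=80 + rep)
            ds = simulate_dataset(ps, sc)
            cpm = ds.counts / ds.counts.sum(0) * 1e6
            diff = (cpm[:, ds.group == 1].mean(1)
                    - cpm[:, ds.group == 0].mean(1))
            nz = diff != 0
            fracs.append((diff[nz] > 0).mean())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        # 3.6 sigma two-sided band, alpha ~ 0.001
        assert abs(fracs.mean() - 0.5) < 3.6 * se

    def test_concentration_reduces_bulk_variance(self):
        """Scaling all Dirichlet alphas up reduces cross-sample count
        variance for fixed expression parameters."""
        import dataclasses
        G = 200
        # strongly distinct cell-type profiles so composition variability
        # dominates the cross-sample count variance
        m = np.tile(np.array([3.0, 6.0, 9.0]), (G, 1))
        v = np.full((G, 3), 0.01)
        gamma = GammaProfileParams(shape=np.repeat((m * m / v)[:, :, None], 2, 2),
                                   rate=np.repeat((m / v)[:, :, None], 2, 2))
        base = build_synthetic_paramset(G, 3, (1.0, 2.0, 3.0), seed=56)
        base = dataclasses.replace(base, gamma=gamma)
        tight = dataclasses.replace(
            base, dirichlet=DirichletParams(alpha=base.dirichlet.alpha * 10))
        sc = ScenarioConfig(n_per_group=100, effect_size=0.0, n_genes=G,
                            seed=81)
        v_base = simulate_dataset(base, sc).counts.var(1)
        v_tight = simulate_dataset(tight, sc).counts.var(1)
        assert np.mean(v_tight < v_base) > 0.8
        assert v_tight.mean() < v_base.mean()

    def test_scenario_validation(self):
        with pytest.raises(InvalidInputError):
            ScenarioConfig(n_per_group=0, effect_size=0.5, n_genes=10)
        with pytest.raises(InvalidInputError):
            ScenarioConfig(n_per_group=5, effect_size=0.5, n_genes=10,
                           de_fraction=1.5)
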