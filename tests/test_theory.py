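import numpy as np
import pytest

from eghr.priors import gaussian_prior, gen_gaussian_prior
from eghr.sources import SourceSpec, make_mixing, make_rotation
from eghr.theory import (
    bs_proximity_check,
    critical_exponent,
    empirical_stability,
    expected_gradient,
    fixed_point_case1,
    fixed_point_case2,
    fixed_point_case3,
    oja_equivalence_check,
    omega_matrix,
    omega_matrix_mc,
    stability_case1,
    stability_case2,
    stability_case3,
)


class TestFixedPointConstruction:
    def test_case1_diagonal(self):
        """PᵀP = Diag[βΛ_ii + (1-β)/(1+κ_i/2)] holds by construction."""
        lam = np.array([4.0, 2.0, 1.0, 0.5])
        kap = np.array([0.0, -1.2, 0.0, -1.2])
        fp = fixed_point_case1(lam, kap, 0.5, 2, C=make_rotation(2, 3))
        D = fp.K[:, :2].T @ fp.K[:, :2]
        np.testing.assert_allclose(np.diag(D), [0.5 * 4 + 0.5, 0.5 * 2 + 0.5 / 0.4], atol=1e-10)
        np.testing.assert_allclose(D - np.diag(np.diag(D)), 0.0, atol=1e-10)
        np.testing.assert_allclose(fp.K[:, 2:], 0.0)

    def test_case1_beta1_reduces_to_eigenvalues(self):
        fp = fixed_point_case1([4.0, 2.0, 1.0], [0.0, 0.0, 0.0], 1.0, 2)
        np.testing.assert_allclose(fp.diagonal, [4.0, 2.0])

    def test_case1_balanced_entry(self):
        # β=0.5, Λ=1, κ=0 → 0.5·1 + 0.5/1 = 1
        fp = fixed_point_case1([1.0, 1.0], [0.0, 0.0], 0.5, 1)
        np.testing.assert_allclose(fp.diagonal, [1.0])

    def test_case1_beta0_uniform_entries(self):
        fp = fixed_point_case1([1.0, 1.0], [-1.2, -1.2], 0.0, 2)
        np.testing.assert_allclose(fp.diagonal, [2.5, 2.5])  # 1/(1 - 1.2/2)

    def test_kurtosis_floor_enforced(self):
        with pytest.raises(ValueError):
            fixed_point_case1([1.0], [-2.5], 0.5, 1)


class TestExpectedGradient:
    def test_case1_fixed_point_residual_vanishes(self):
        specs = [SourceSpec("gaussian"), SourceSpec("uniform"),
                 SourceSpec("gaussian"), SourceSpec("uniform")]
        lam = np.array([4.0, 2.0, 1.0, 0.5])
        kap = np.array([s.kurtosis for s in specs])
        fp = fixed_point_case1(lam, kap, 0.5, 2, C=make_rotation(2, 3), source_specs=specs)
        g, se = expected_gradient(fp.K, lam, fp.prior, 0.5, specs, 300_000, 11)
        assert np.abs(g / se).max() < 4.0

    def test_case2_fixed_point_residual_vanishes(self):
        prior = gen_gaussian_prior(4)
        specs = [SourceSpec("gen_gaussian", a=4)] * 2 + [SourceSpec("gaussian"), SourceSpec("uniform")]
        fp = fixed_point_case2(prior, specs)
        g, se = expected_gradient(fp.K, fp.eigenvalues, prior, 0.0, specs, 300_000, 12)
        assert np.abs(g / se).max() < 4.0

    def test_random_point_has_large_residual(self):
        prior = gen_gaussian_prior(4)
        specs = [SourceSpec("gen_gaussian", a=4)] * 3
        K = np.random.default_rng(5).normal(size=(2, 3))
        g, se = expected_gradient(K, np.ones(3), prior, 0.0, specs, 50_000, 13)
        assert np.abs(g / se).max() > 10.0

    def test_standard_errors_shrink_like_sqrt_n(self):
        prior = gaussian_prior()
        specs = [SourceSpec("gaussian")] * 3
        K = np.array([[1.0, 0.2, 0.0]])
        ses = []
        for n in (10_000, 40_000, 160_000):
            _, se = expected_gradient(K, np.ones(3), prior, 1.0, specs, n, 7)
            ses.append(se.mean())
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.2)
        assert ses[1] / ses[2] == pytest.approx(2.0, rel=0.2)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            expected_gradient(np.eye(2), np.ones(2), gaussian_prior(), 0.5,
                              [SourceSpec("gaussian")] * 2, 500, 0)


class TestStabilityPredicates:
    def test_case1_pca_margin(self):
        v = stability_case1([4.0, 2.0], [0.0, 0.0], 1.0, 1)
        assert v.stable and v.min_margin == pytest.approx(2.0)

    def test_case1_ica_sub_gaussian_stable(self):
        v = stability_case1([1.0, 1.0], [-1.2, 0.0], 0.0, 1)
        assert v.stable and v.min_margin == pytest.approx(1.5)

    def test_case1_ica_super_gaussian_unstable(self):
        v = stability_case1([1.0, 1.0], [1.0, 0.0], 0.0, 1)
        assert not v.stable and v.min_margin == pytest.approx(1 / 1.5 - 1)

    def test_case1_gaussian_beta1_is_eigenvalue_ordering(self):
        assert stability_case1([2.0, 1.0], [0.0, 0.0], 1.0, 1).stable
        assert not stability_case1([1.0, 2.0], [0.0, 0.0], 1.0, 1).stable

    def test_case2_flip_across_a_equals_2(self):
        for a, expect in ((1.5, False), (3.0, True), (4.0, True)):
            prior = gen_gaussian_prior(a)
            specs = [SourceSpec("gen_gaussian", a=a)] * 2 + [SourceSpec("gaussian")]
            v = stability_case2(omega_matrix(prior, specs, 2), 2, 3)
            assert v.stable is expect, f"a={a}"

    def test_gaussian_prior_boundary_is_marginal(self):
        """a = 2 sits exactly on the stability boundary."""
        prior = gen_gaussian_prior(2.0)
        specs = [SourceSpec("gen_gaussian", a=2.0)] * 2 + [SourceSpec("gaussian")]
        v = stability_case2(omega_matrix(prior, specs, 2), 2, 3)
        assert abs(v.min_margin) < 1e-8
        assert v.marginal and not v.stable

    def test_omega_quadrature_matches_monte_carlo(self):
        prior = gen_gaussian_prior(4)
        specs = [SourceSpec("gen_gaussian", a=4)] * 2 + [SourceSpec("gaussian")]
        om = omega_matrix(prior, specs, 2)
        om_mc, se = omega_matrix_mc(prior, specs, 2, 500_000, 7)
        assert np.abs((om - om_mc) / se).max() < 4.0

    def test_omega_sign_flip_invariance(self):
        """Even source distributions make Ω invariant to sign conventions:
        quadrature over s and -s agree (checked via Monte-Carlo symmetry)."""
        prior = gen_gaussian_prior(3)
        specs = [SourceSpec("gen_gaussian", a=3)] * 2
        rng = np.random.default_rng(0)
        om1, _ = omega_matrix_mc(prior, specs, 2, 200_000, 1)
        om2, se = omega_matrix_mc(prior, specs, 2, 200_000, 2)
        assert np.abs((om1 - om2) / se).max() < 6.0  # same Ω from independent draws

    def test_case3_beta0_reduces_to_sign_of_a_minus_2(self):
        for a in (1.5, 3.0, 4.0):
            v3 = stability_case3([1.0, 1.0], [0.0, 0.0], a, 0.0, 1)
            assert v3.stable is (a > 2.0)

    def test_case3_beta1_kappa0_matches_case1(self):
        v3 = stability_case3([4.0, 2.0, 1.0], [0.0, 0.0, 0.0], 2.0, 1.0, 2)
        v1 = stability_case1([4.0, 2.0, 1.0], [0.0, 0.0, 0.0], 1.0, 2)
        for k in v1.margins:
            assert v3.margins[k] == pytest.approx(v1.margins[k], abs=1e-9)


class TestCriticalExponent:
    def test_flip_is_at_two(self):
        a_star = critical_exponent(lo=1.5, hi=3.0, tol=1e-3)
        assert abs(a_star - 2.0) < 1e-3


class TestEmpiricalStability:
    def test_zero_perturbation_stays_put(self):
        prior = gen_gaussian_prior(4)
        specs = [SourceSpec("gen_gaussian", a=4)] * 2 + [SourceSpec("gaussian")]
        fp = fixed_point_case2(prior, specs)
        r = empirical_stability(fp, perturbation=0.0, n_samples=20_000, n_iter=50, seed=1)
        assert r["trajectory"][0] == 0.0

    @pytest.mark.parametrize("a, expect", [(3.0, "decaying"), (1.5, "growing")])
    def test_case2_classification(self, a, expect):
        prior = gen_gaussian_prior(a)
        specs = [SourceSpec("gen_gaussian", a=a)] * 2 + [SourceSpec("gaussian")]
        fp = fixed_point_case2(prior, specs)
        r = empirical_stability(fp, n_samples=50_000, n_iter=400, seed=2)
        assert r["classification"] == expect


class TestRuleEquivalences:
    def test_pca_term_equals_oja_times_AAt_for_gaussian_sources(self):
        mm = make_mixing(make_rotation(4, 1), [4.0, 2.0, 1.0, 0.5])
        W = np.random.default_rng(0).normal(scale=0.5, size=(2, 4))
        r = oja_equivalence_check(W, mm, 300_000, 2)
        assert r["max_z"] < 4.0

    def test_bussgang_identity_fails_for_uniform_sources(self):
        mm = make_mixing(make_rotation(4, 1), [4.0, 2.0, 1.0, 0.5])
        W = np.random.default_rng(0).normal(scale=0.5, size=(2, 4))
        r = oja_equivalence_check(W, mm, 300_000, 2, source_specs=[SourceSpec("uniform")] * 4)
        assert r["max_z"] > 10.0

    def test_ica_term_close_to_bell_sejnowski_second_order(self):
        scales = np.logspace(-2.2, -1, 6)
        _, slope = bs_proximity_check(scales, a=4, n_samples=400_000, seed=3)
        assert slope == pytest.approx(2.0, abs=0.4)

    def test_mismatched_sources_degrade_to_first_order(self):
        scales = np.logspace(-2.2, -1, 6)
        _, slope = bs_proximity_check(scales, a=4, n_samples=400_000, seed=3, mismatch=True)
        assert slope < 1.5
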