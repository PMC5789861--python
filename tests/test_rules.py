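import numpy as np
import pytest

from eghr.metrics import eghr_cost
from eghr.priors import gaussian_prior, gen_gaussian_prior, uniform_surrogate_prior
from eghr.rules import (
    NetworkState,
    RuleConfig,
    baseline_update,
    eghr_batch_gradient,
    eghr_beta_update,
    expected_source_energy,
    global_factors,
    make_generative_stream,
    original_eghr_update,
    train,
)
from eghr.sources import SourceSpec, make_mixing, make_rotation

from conftest import finite_difference_gradient


class TestGlobalFactors:
    def test_centered_definitions(self, quartic_prior):
        state = NetworkState(W=np.eye(2), mean_u2=2.0, mean_x2=3.0, mean_E=0.7)
        u = np.array([2.0, 0.0])
        x = np.array([1.0, 1.0])
        E, E_u, E_x, E_0 = global_factors(state, quartic_prior, u, x)
        assert E_u == pytest.approx(1.0)  # (4 - 2)/2, direct substitution
        assert E_x == pytest.approx(-0.5)
        assert E_0 == pytest.approx(1.7)
        # |u|² equal to the running mean gives a vanishing E_u
        _, E_u0, _, _ = global_factors(state, quartic_prior, np.array([np.sqrt(2), 0.0]), x)
        assert E_u0 == pytest.approx(0.0)

    def test_gaussian_energy_minimum_at_zero(self):
        p = gaussian_prior()
        assert p.energy(np.zeros(3)) < p.energy(np.full(3, 0.1))

    def test_nonfinite_rejected(self, quartic_prior):
        state = NetworkState(W=np.eye(2))
        with pytest.raises(FloatingPointError):
            global_factors(state, quartic_prior, np.array([np.nan, 0.0]), np.zeros(2))


class TestGradientOracles:
    """Every gradient-based rule must match central finite differences of
    its stated cost on a fixed batch."""

    @pytest.mark.parametrize("beta", [0.0, 0.3, 0.5, 1.0])
    def test_eghr_matches_cost_gradient(self, beta, mixed_batch, quartic_prior, rng):
        W = rng.normal(scale=0.5, size=(2, 3))
        g = eghr_batch_gradient(W, quartic_prior, beta, mixed_batch)
        fd = finite_difference_gradient(
            lambda Wm: eghr_cost(mixed_batch, Wm, quartic_prior, beta)[0], W
        )
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-4

    def test_original_eghr_matches_its_cost(self, mixed_batch, quartic_prior, rng):
        specs = [SourceSpec("gen_gaussian", a=4)] * 3
        Es = expected_source_energy(quartic_prior, specs)
        W = rng.normal(scale=0.5, size=(2, 3))
        state = NetworkState(W=W)
        dW = original_eghr_update(state, quartic_prior, mixed_batch, Es)

        def cost(Wm):
            E = quartic_prior.energy(mixed_batch @ Wm.T)
            return 0.5 * np.mean((E - Es - 1.0) ** 2)

        fd = finite_difference_gradient(cost, W)
        assert np.abs(-dW - fd).max() / np.abs(fd).max() < 1e-4

    def test_cost_decomposition_identity(self, mixed_batch, quartic_prior, rng):
        """The original rule's cost equals the ICA part plus the squared
        mean-energy mismatch plus a constant, on any fixed sample set."""
        specs = [SourceSpec("gen_gaussian", a=4)] * 3
        Es = expected_source_energy(quartic_prior, specs)
        W = rng.normal(scale=0.5, size=(3, 3))
        E = quartic_prior.energy(mixed_batch @ W.T)
        lhs = 0.5 * np.mean((E - Es - 1.0) ** 2)
        ica = np.mean(0.5 * (E - E.mean()) ** 2 - E)
        const = Es + 0.5
        assert lhs == pytest.approx(ica + 0.5 * (E.mean() - Es) ** 2 + const, rel=1e-12)

    def test_original_equals_beta0_when_energies_agree(self, mixed_batch, quartic_prior, rng):
        W = rng.normal(scale=0.5, size=(2, 3))
        E_mean = float(np.mean(quartic_prior.energy(mixed_batch @ W.T)))
        state = NetworkState(W=W, mean_E=E_mean)
        d_orig = original_eghr_update(state, quartic_prior, mixed_batch, E_mean)
        d_beta0 = eghr_beta_update(state, quartic_prior, 0.0, mixed_batch, tau=None)
        np.testing.assert_allclose(d_orig, d_beta0, atol=1e-12)

    def test_xu_matches_reconstruction_cost(self, mixed_batch, quartic_prior, rng):
        W = rng.normal(scale=0.5, size=(3, 3))
        dW = baseline_update("xu", W, quartic_prior, mixed_batch)

        def cost(Wm):
            R = mixed_batch - mixed_batch @ Wm.T @ Wm
            return 0.5 * np.mean(np.sum(R * R, axis=1))

        fd = finite_difference_gradient(cost, W)
        assert np.abs(-dW - fd).max() / np.abs(fd).max() < 1e-4

    def test_bell_sejnowski_matches_kl_cost(self, mixed_batch, quartic_prior, rng):
        W = rng.normal(scale=0.5, size=(3, 3))
        dW = baseline_update("bell_sejnowski", W, quartic_prior, mixed_batch)

        def cost(Wm):
            return -np.linalg.slogdet(Wm)[1] + np.mean(quartic_prior.energy(mixed_batch @ Wm.T))

        fd = finite_difference_gradient(cost, W)
        assert np.abs(-dW - fd).max() / np.abs(fd).max() < 1e-4

    def test_amari_is_natural_gradient_of_bell_sejnowski(self, mixed_batch, quartic_prior, rng):
        W = rng.normal(scale=0.5, size=(3, 3))
        d_bs = baseline_update("bell_sejnowski", W, quartic_prior, mixed_batch)
        d_am = baseline_update("amari", W, quartic_prior, mixed_batch)
        np.testing.assert_allclose(d_am, d_bs @ (W.T @ W), atol=1e-12)


class TestUpdateProperties:
    def test_affine_in_beta(self, mixed_batch, quartic_prior, rng):
        W = rng.normal(scale=0.5, size=(2, 3))
        state = NetworkState(W=W, mean_u2=1.0, mean_x2=2.0, mean_E=0.5)
        d0 = eghr_beta_update(state, quartic_prior, 0.0, mixed_batch, tau=None)
        d1 = eghr_beta_update(state, quartic_prior, 1.0, mixed_batch, tau=None)
        for beta in (0.25, 0.6, 0.9):
            db = eghr_beta_update(state, quartic_prior, beta, mixed_batch, tau=None)
            np.testing.assert_allclose(db, (1 - beta) * d0 + beta * d1, atol=1e-12)

    def test_zero_input_gives_zero_update(self, quartic_prior):
        state = NetworkState(W=np.ones((2, 3)), mean_u2=1.0, mean_x2=1.0, mean_E=0.2)
        d = eghr_beta_update(state, quartic_prior, 0.5, np.zeros((4, 3)), tau=None)
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_empty_batch_rejected(self, quartic_prior):
        state = NetworkState(W=np.eye(2))
        with pytest.raises(ValueError):
            eghr_beta_update(state, quartic_prior, 0.0, np.empty((0, 2)), tau=None)
        with pytest.raises(ValueError):
            baseline_update("oja", np.eye(2), quartic_prior, np.empty((0, 2)))

    def test_update_locality(self, mixed_batch, quartic_prior, rng):
        """ΔW_ij is reconstructible from x_j, u_i, and the global scalars
        alone — the locality property of the three-factor rule."""
        W = rng.normal(scale=0.5, size=(2, 3))
        x = mixed_batch[0]
        u = W @ x
        state = NetworkState(W=W, mean_u2=1.3, mean_x2=2.1, mean_E=0.4)
        beta = 0.35
        d = eghr_beta_update(state, quartic_prior, beta, x[None, :], tau=None)
        E, E_u, E_x, E_0 = global_factors(state, quartic_prior, u, x)
        i, j = 1, 2
        local = -((1 - beta) * (E - E_0) * quartic_prior.g(u[i]) * x[j]
                  + beta * (E_u - E_x) * u[i] * x[j])
        assert d[i, j] == pytest.approx(local, rel=1e-12)

    def test_oja_stationary_at_principal_subspace(self, rng):
        """At W = top-N eigenvector rows the expected Oja update vanishes."""
        mixing = make_mixing(make_rotation(4, 9), [4.0, 2.0, 1.0, 0.5])
        cov = mixing.A @ mixing.A.T
        w, V = np.linalg.eigh(cov)
        W = V[:, np.argsort(w)[::-1][:2]].T
        S = np.column_stack([SourceSpec("gaussian").sample(400_000, rng) for _ in range(4)])
        X = mixing.mix(S)
        d = baseline_update("oja", W, gaussian_prior(), X)
        assert np.abs(d).max() < 0.02

    def test_amari_stationary_at_ica_solution(self, rng):
        """With outputs drawn from the matched prior and K = I the expected
        Amari update vanishes."""
        prior = gen_gaussian_prior(4)
        S = np.column_stack([SourceSpec("gen_gaussian", a=4).sample(400_000, rng) for _ in range(3)])
        d = baseline_update("amari", np.eye(3), prior, S)
        assert np.abs(d).max() < 0.02

    def test_nonsquare_bell_sejnowski_rejected(self, quartic_prior):
        with pytest.raises(ValueError):
            baseline_update("bell_sejnowski", np.ones((2, 3)), quartic_prior, np.ones((5, 3)))


class TestTraining:
    def _stream(self, seed=0):
        specs = [SourceSpec("gaussian"), SourceSpec("uniform")]
        mixing = make_mixing(make_rotation(2, 5), [2.0, 1.0])
        return make_generative_stream(mixing, specs, seed), specs

    def test_zero_learning_rate_keeps_initial_weights(self, quartic_prior):
        stream, _ = self._stream()
        W0 = np.array([[0.3, -0.2], [0.1, 0.4]])
        cfg = RuleConfig(rule="eghr_beta", beta=0.5, eta=0.0, steps=5000, batch_size=10, seed=1)
        W, _ = train(stream, cfg, quartic_prior, 2, n_inputs=2, W0=W0)
        np.testing.assert_array_equal(W, W0)

    def test_training_is_deterministic(self, quartic_prior):
        runs = []
        for _ in range(2):
            stream, _ = self._stream(seed=3)
            cfg = RuleConfig(rule="eghr_beta", beta=0.0, eta=1e-5, steps=20_000,
                             batch_size=10, seed=4)
            W, _ = train(stream, cfg, quartic_prior, 2, n_inputs=2)
            runs.append(W)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_divergence_guard_raises(self, quartic_prior):
        stream, _ = self._stream()
        cfg = RuleConfig(rule="eghr_beta", beta=0.0, eta=10.0, steps=200_000,
                         batch_size=10, seed=2, divergence_norm=100.0, log_every=100)
        with pytest.raises(RuntimeError, match="diverged"):
            train(stream, cfg, quartic_prior, 2, n_inputs=2)

    def test_running_estimates_track_true_expectations(self, quartic_prior):
        """With eta = 0 the EMA state converges to the true moments of a
        stationary stream."""
        stream, _ = self._stream(seed=8)
        X = stream(200_000)
        state = NetworkState(W=np.eye(2) * 0.5)
        state.warm_up(X[:1000], quartic_prior)
        for k in range(1000, 200_000, 500):
            batch = X[k : k + 500]
            state.update_running(batch, batch @ state.W.T, quartic_prior, tau=1e4)
        U = X @ state.W.T
        assert state.mean_u2 == pytest.approx(np.mean(np.sum(U * U, axis=1)), rel=0.1)
        assert state.mean_x2 == pytest.approx(np.mean(np.sum(X * X, axis=1)), rel=0.1)
        assert state.mean_E == pytest.approx(np.mean(quartic_prior.energy(U)), rel=0.1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig(rule="hebbian_deluxe")
        with pytest.raises(ValueError):
            RuleConfig(beta=1.5)
        with pytest.raises(ValueError):
            RuleConfig(steps=0)
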