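"""Online learning rules: error-gated Hebbian rule and non-local baselines.

The network is a single linear layer u = W x (N outputs, M inputs).  The
error-gated rule minimizes

    L = (1-β) ⟨ (E(u) - ⟨E(u)⟩)²/2 - E(u) ⟩   (ICA term)
      +   β   ⟨ (E_u(u) - E_x(x))²/2 ⟩         (PCA term)

with E(u) = -log p0(u), E_u = (|u|² - ⟨|u|²⟩)/2, E_x = (|x|² - ⟨|x|²⟩)/2.
Its stochastic gradient descent is local: each synapse W_ij changes by the
product of presynaptic activity x_j, a postsynaptic factor (g(u_i) or u_i),
and globally broadcast scalars,

    ΔW = -[(1-β)(E(u) - E_0) g(u) xᵀ + β (E_u - E_x) u xᵀ],   E_0 = 1 + ⟨E(u)⟩.

Expectations ⟨·⟩ are estimated either by exponential moving averages (the
online, biologically consistent default) or by per-batch means (exact batch
semantics, used by the gradient-oracle tests and the theory module).

Baselines for comparison are Oja's subspace rule, Xu's least-mean-squared-
error PCA, Bell-Sejnowski's ICA rule, Amari's natural-gradient ICA rule,
and a two-layer Oja→Amari cascade.  All of these are non-local.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .priors import PriorSpec

__all__ = [
    "NetworkState",
    "RuleConfig",
    "TrainLog",
    "global_factors",
    "eghr_beta_update",
    "eghr_batch_gradient",
    "original_eghr_update",
    "baseline_update",
    "expected_source_energy",
    "make_generative_stream",
    "train",
]

RULES = ("eghr_beta", "eghr_original", "oja", "xu", "bell_sejnowski", "amari", "cascade")


# ---------------------------------------------------------------------------
# state and configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Synaptic matrix plus the running estimates behind the global factors."""

    W: np.ndarray
    mean_u2: float = 0.0  # running ⟨|u|²⟩
    mean_x2: float = 0.0  # running ⟨|x|²⟩
    mean_E: float = 0.0   # running ⟨E(u)⟩
    step: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(self.W.copy(), self.mean_u2, self.mean_x2, self.mean_E, self.step)

    def warm_up(self, X: np.ndarray, prior: PriorSpec) -> None:
        """Initialize the running estimates from a pre-pass sample block."""
        U = X @ self.W.T
        self.mean_u2 = float(np.mean(np.sum(U * U, axis=1)))
        self.mean_x2 = float(np.mean(np.sum(X * X, axis=1)))
        self.mean_E = float(np.mean(prior.energy(U)))

    def update_running(self, X: np.ndarray, U: np.ndarray, prior: PriorSpec, tau: float) -> None:
        """EMA update with per-sample time constant tau, applied once per batch."""
        B = X.shape[0]
        w = 1.0 - (1.0 - 1.0 / tau) ** B
        self.mean_u2 += w * (float(np.mean(np.sum(U * U, axis=1))) - self.mean_u2)
        self.mean_x2 += w * (float(np.mean(np.sum(X * X, axis=1))) - self.mean_x2)
        self.mean_E += w * (float(np.mean(prior.energy(U))) - self.mean_E)


@dataclass(frozen=True)
class RuleConfig:
    """Configuration of one training run.

    ``eta`` is the per-sample learning rate; a minibatch of size B applies
    B·eta times the batch-mean update so trajectories are comparable across
    batch sizes.  ``tau`` is the EMA time constant (samples) of the running
    expectations; ``warmup`` samples initialize them before learning.
    """

    rule: str = "eghr_beta"
    beta: float = 0.0
    eta: float = 8e-6
    steps: int = 2_000_000
    batch_size: int = 1
    tau: float = 1e4
    init: str = "gaussian"     # "gaussian" | "identity"
    init_scale: float = 0.25   # variance of Gaussian init entries
    seed: int | None = None
    warmup: int = 1000
    log_every: int = 50_000
    divergence_norm: float = 1e6

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.eta < 0:
            raise ValueError("learning rate must be non-negative")
        if self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# updates
# ---------------------------------------------------------------------------

def global_factors(state: NetworkState, prior: PriorSpec, u: np.ndarray, x: np.ndarray):
    """Global error factors (E, E_u, E_x, E_0) for one sample or batch.

    E_u and E_x are centered with the state's running estimates; E_0 is
    1 + the running mean of E(u).
    """
    u = np.asarray(u, float)
    x = np.asarray(x, float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(x))):
        raise FloatingPointError("non-finite activity passed to global_factors")
    E = prior.energy(u)
    E_u = 0.5 * (np.sum(u * u, axis=-1) - state.mean_u2)
    E_x = 0.5 * (np.sum(x * x, axis=-1) - state.mean_x2)
    return E, E_u, E_x, 1.0 + state.mean_E


def _eghr_delta(W, prior, beta, X, mean_u2, mean_x2, E0):
    """Batch-mean EGHR update (negated gradient) at fixed expectation values."""
    U = X @ W.T
    n = X.shape[0]
    grad = np.zeros_like(W)
    if beta < 1.0:
        E = prior.energy(U)
        grad += (1.0 - beta) * ((E - E0)[:, None] * prior.g(U)).T @ X / n
    if beta > 0.0:
        eu = 0.5 * (np.sum(U * U, axis=1) - mean_u2)
        ex = 0.5 * (np.sum(X * X, axis=1) - mean_x2)
        grad += beta * ((eu - ex)[:, None] * U).T @ X / n
    return -grad


def eghr_beta_update(
    state: NetworkState,
    prior: PriorSpec,
    beta: float,
    batch: np.ndarray,
    tau: float | None = None,
) -> np.ndarray:
    """EGHR-β update ΔW for one minibatch (pre-learning-rate).

    With ``tau`` given, the running estimates in ``state`` are EMA-updated
    once from the batch before the factors are evaluated (online mode);
    with ``tau=None`` the state's current estimates are used as-is.
    β = 0 gives the pure ICA term, β = 1 the pure PCA term, and the update
    is affine in β between them.
    """
    X = np.atleast_2d(np.asarray(batch, float))
    if X.size == 0:
        raise ValueError("empty batch")
    if tau is not None:
        state.update_running(X, X @ state.W.T, prior, tau)
    return _eghr_delta(state.W, prior, beta, X, state.mean_u2, state.mean_x2, 1.0 + state.mean_E)


def eghr_batch_gradient(W: np.ndarray, prior: PriorSpec, beta: float, X: np.ndarray) -> np.ndarray:
    """Exact gradient ∂L/∂W of the batch cost, all expectations = batch means.

    The returned matrix is the *gradient*; the learning update is its
    negation.  Because the centering terms average to zero, the analytic
    batch gradient coincides with the simple per-sample form even though
    ⟨E⟩, ⟨|u|²⟩, ⟨|x|²⟩ themselves depend on W.
    """
    X = np.atleast_2d(np.asarray(X, float))
    U = X @ W.T
    mean_u2 = float(np.mean(np.sum(U * U, axis=1)))
    mean_x2 = float(np.mean(np.sum(X * X, axis=1)))
    E0 = 1.0 + float(np.mean(prior.energy(U)))
    return -_eghr_delta(W, prior, beta, X, mean_u2, mean_x2, E0)


def expected_source_energy(prior: PriorSpec, source_specs) -> float:
    """⟨E(s)⟩ = Σ_i ∫ p_i(s) (-log p0(s)) ds by adaptive quadrature."""
    total = 0.0
    for spec in source_specs:
        val, _ = integrate.quad(lambda s, sp=spec: sp.pdf(s) * prior.energy1(s), -np.inf, np.inf)
        total += val
    return float(total)


def original_eghr_update(
    state: NetworkState,
    prior: PriorSpec,
    batch: np.ndarray,
    source_energy: float,
) -> np.ndarray:
    """Original error-gated Hebbian update (ICA only).

    Identical to the β = 0 update except that the reference level is fixed
    at E_0 = 1 + ⟨E(s)⟩ computed from the *source* prior rather than
    tracking 1 + ⟨E(u)⟩.  Its cost is ⟨(E(u) - ⟨E(s)⟩ - 1)²⟩/2.
    """
    X = np.atleast_2d(np.asarray(batch, float))
    if X.size == 0:
        raise ValueError("empty batch")
    return _eghr_delta(state.W, prior, 0.0, X, 0.0, 0.0, 1.0 + source_energy)


def baseline_update(rule: str, W: np.ndarray, prior: PriorSpec, batch: np.ndarray) -> np.ndarray:
    """Batch estimate of a comparison rule's update ΔW (pre-learning-rate).

    oja:             ⟨u (xᵀ - uᵀ W)⟩
    xu:              ⟨u (xᵀ - uᵀ W) + (u - W Wᵀ u) xᵀ⟩   (−∂/∂W of ⟨|x - Wᵀu|²⟩/2)
    bell_sejnowski:  W^{-T} - ⟨g(u) xᵀ⟩                  (W square, invertible)
    amari:           W - ⟨g(u) uᵀ⟩ W                     (natural gradient)
    """
    X = np.atleast_2d(np.asarray(batch, float))
    if X.size == 0:
        raise ValueError("empty batch")
    n = X.shape[0]
    U = X @ W.T
    if rule == "oja":
        return (U.T @ X - (U.T @ U) @ W) / n
    if rule == "xu":
        R = X - U @ W  # residual x - Wᵀu
        return (U.T @ R + (U - U @ W @ W.T).T @ X) / n
    if rule == "bell_sejnowski":
        if W.shape[0] != W.shape[1]:
            raise ValueError("Bell-Sejnowski's rule requires square W")
        return np.linalg.inv(W).T - prior.g(U).T @ X / n
    if rule == "amari":
        return W - (prior.g(U).T @ U / n) @ W
    raise ValueError(f"unknown baseline rule {rule!r}")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainLog:
    """Time series recorded during training."""

    records: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def append(self, **kw) -> None:
        self.records.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def make_generative_stream(mixing, source_specs, seed, block: int = 262_144):
    """Batch sampler drawing x = A s from the generative model.

    Samples are produced in large blocks and served in order, which keeps
    small-minibatch training fast without changing the stream's law.
    """
    rng = np.random.default_rng(seed)
    A_T = mixing.A.T
    buf = {"X": np.empty((0, mixing.M)), "pos": 0}

    def refill(n):
        m = max(block, n)
        S = np.column_stack([spec.sample(m, rng) for spec in source_specs])
        buf["X"] = S @ A_T
        buf["pos"] = 0

    def sample(n):
        if buf["pos"] + n > buf["X"].shape[0]:
            refill(n)
        out = buf["X"][buf["pos"] : buf["pos"] + n]
        buf["pos"] += n
        return out

    return sample


def _init_W(config: RuleConfig, n_outputs: int, n_inputs: int, rng) -> np.ndarray:
    if config.init == "identity":
        W = np.zeros((n_outputs, n_inputs))
        W[:, :n_outputs] = np.eye(n_outputs)
        if n_outputs == n_inputs:
            W = np.eye(n_outputs)
        return W
    if config.init == "gaussian":
        return rng.normal(0.0, np.sqrt(config.init_scale), size=(n_outputs, n_inputs))
    raise ValueError(f"unknown init scheme {config.init!r}")


def train(
    stream,
    config: RuleConfig,
    prior: PriorSpec,
    n_outputs: int,
    n_inputs: int | None = None,
    W0: np.ndarray | None = None,
    source_specs=None,
):
    """Run one training session and return ``(W, TrainLog)``.

    Parameters
    ----------
    stream : callable or MixedImageStream
        ``stream(n)`` (or ``stream.sample(n)``) must return an (n, M) batch
        of input vectors.
    config : RuleConfig
        Rule name, β, learning rate, step/batch/EMA settings, seed.
    prior : PriorSpec
        Output prior for the error-gated and ICA rules.
    n_outputs : int
        N, the number of output channels.
    W0 : ndarray, optional
        Explicit initial weights (overrides the config's init scheme).
    source_specs : list of SourceSpec, optional
        Required for ``rule="eghr_original"`` to fix E_0 from ⟨E(s)⟩.

    ``config.steps`` counts input samples; updates are applied per
    minibatch with effective step size ``eta * batch_size``.  A run whose
    ‖W‖_F exceeds ``config.divergence_norm`` raises RuntimeError naming
    the sample index.
    """
    sample = stream.sample if hasattr(stream, "sample") else stream
    rng = np.random.default_rng(config.seed)
    if n_inputs is None:
        n_inputs = np.atleast_2d(sample(1)).shape[1]

    cascade = config.rule == "cascade"
    if W0 is not None:
        W = np.array(W0, dtype=float)
    else:
        W = _init_W(config, n_outputs, n_inputs, rng)
    W2 = np.eye(n_outputs) if cascade else None

    state = NetworkState(W=W)
    if config.rule in ("eghr_beta", "eghr_original"):
        state.warm_up(np.atleast_2d(sample(config.warmup)), prior)
    source_energy = None
    if config.rule == "eghr_original":
        if source_specs is None:
            raise ValueError("eghr_original needs source_specs to fix E_0 = 1 + ⟨E(s)⟩")
        source_energy = expected_source_energy(prior, source_specs)

    log = TrainLog()
    B = config.batch_size
    eta_eff = config.eta * B
    n_updates = int(np.ceil(config.steps / B))
    next_log = 0
    for it in range(n_updates):
        X = np.atleast_2d(sample(B))
        step = it * B
        if step >= next_log:
            wn = float(np.linalg.norm(state.W))
            log.append(step=step, w_norm=wn, mean_u2=state.mean_u2,
                       mean_x2=state.mean_x2, mean_E=state.mean_E)
            next_log += config.log_every
            if not np.isfinite(wn) or wn > config.divergence_norm:
                raise RuntimeError(f"training diverged at sample {step}: ||W||_F = {wn:.3g}")
        if config.eta == 0.0:
            continue
        if config.rule == "eghr_beta":
            dW = eghr_beta_update(state, prior, config.beta, X, tau=config.tau)
            state.W += eta_eff * dW
        elif config.rule == "eghr_original":
            dW = original_eghr_update(state, prior, X, source_energy)
            state.W += eta_eff * dW
        elif cascade:
            Y = X @ state.W.T
            state.W += eta_eff * baseline_update("oja", state.W, prior, X)
            W2 += eta_eff * baseline_update("amari", W2, prior, Y)
        else:
            state.W += eta_eff * baseline_update(config.rule, state.W, prior, X)
        state.step = step + B

    W_final = state.W
    if cascade:
        log.extras["W1"] = state.W.copy()
        log.extras["W2"] = W2.copy()
        W_final = W2 @ state.W
    wn = float(np.linalg.norm(W_final))
    if not np.isfinite(wn) or wn > config.divergence_norm:
        raise RuntimeError(f"training diverged by sample {state.step}: ||W||_F = {wn:.3g}")
    log.append(step=state.step, w_norm=wn, mean_u2=state.mean_u2,
               mean_x2=state.mean_x2, mean_E=state.mean_E)
    log.extras["state"] = state
    return W_final, log
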