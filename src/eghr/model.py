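"""Model/Results interface for blind-source-separation training runs.

`HebbianBSS` bundles a data source (a generative mixing model or a mixed
image stream), an output dimension, a learning rule, and an output prior;
``fit()`` runs the online learning and returns a `HebbianBSSResults`
carrying the learned unmixing matrix, the training log, and evaluation
helpers (source-matching correlations, costs, principal angles, summary
table, output plots).
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .priors import PriorSpec, uniform_surrogate_prior
from .rules import RuleConfig, TrainLog, make_generative_stream, train
from .sources import ImageSourceSet, MixedImageStream, MixingModel, mix_images

__all__ = ["HebbianBSS", "HebbianBSSResults"]


class HebbianBSS:
    """Single-layer blind-source-separation model u = W x.

    Construct with :meth:`from_generative` (sources + mixing matrix) or
    :meth:`from_images` (image sources + rotation).  The learning rule,
    its PCA weight β, and the assumed output prior are model properties;
    optimization settings (steps, learning rate, batching) belong to
    :meth:`fit`.
    """

    def __init__(
        self,
        stream,
        n_inputs: int,
        n_outputs: int,
        rule: str = "eghr_beta",
        beta: float = 0.0,
        prior: PriorSpec | None = None,
        mixing: MixingModel | None = None,
        source_specs=None,
        image_stream: MixedImageStream | None = None,
    ):
        self.stream = stream
        self.n_inputs = n_inputs
        self.n_outputs = n_outputs
        self.rule = rule
        self.beta = beta
        self.prior = prior if prior is not None else uniform_surrogate_prior()
        self.mixing = mixing
        self.source_specs = source_specs
        self.image_stream = image_stream

    # ------------------------------------------------------------------
    @classmethod
    def from_generative(
        cls,
        mixing: MixingModel,
        source_specs,
        n_outputs: int,
        rule: str = "eghr_beta",
        beta: float = 0.0,
        prior: PriorSpec | None = None,
        seed=None,
    ) -> "HebbianBSS":
        """Model trained on x = A s with s drawn from ``source_specs``."""
        stream = make_generative_stream(mixing, source_specs, seed)
        return cls(
            stream, mixing.M, n_outputs, rule=rule, beta=beta, prior=prior,
            mixing=mixing, source_specs=source_specs,
        )

    @classmethod
    def from_images(
        cls,
        images: ImageSourceSet,
        rotation: np.ndarray,
        n_outputs: int,
        rule: str = "eghr_beta",
        beta: float = 0.0,
        prior: PriorSpec | None = None,
        seed=None,
    ) -> "HebbianBSS":
        """Model trained on rotated pixel columns of an image source set."""
        stream = mix_images(images, rotation, seed=seed)
        return cls(
            stream, stream.dim, n_outputs, rule=rule, beta=beta, prior=prior,
            image_stream=stream,
        )

    # ------------------------------------------------------------------
    def fit(
        self,
        steps: int = 2_000_000,
        learning_rate: float = 8e-6,
        batch_size: int = 20,
        tau: float = 1e4,
        init: str = "gaussian",
        init_scale: float = 0.25,
        seed=None,
        W0: np.ndarray | None = None,
        warmup: int = 1000,
        log_every: int = 50_000,
    ) -> "HebbianBSSResults":
        """Train for ``steps`` input samples and return the results object.

        ``learning_rate`` is per sample; minibatches of ``batch_size``
        apply the batch-mean update scaled by the batch size, so the
        trajectory is comparable across batch sizes.
        """
        config = RuleConfig(
            rule=self.rule, beta=self.beta, eta=learning_rate, steps=steps,
            batch_size=batch_size, tau=tau, init=init, init_scale=init_scale,
            seed=seed, warmup=warmup, log_every=log_every,
        )
        W, log = train(
            self.stream, config, self.prior, self.n_outputs,
            n_inputs=self.n_inputs, W0=W0, source_specs=self.source_specs,
        )
        return HebbianBSSResults(self, W, log, config)


class HebbianBSSResults:
    """Results of a fitted `HebbianBSS` model."""

    def __init__(self, model: HebbianBSS, W: np.ndarray, log: TrainLog, config: RuleConfig):
        self.model = model
        self.W = W
        self.train_log = log
        self.config = config

    @property
    def params(self) -> np.ndarray:
        """The learned unmixing (synaptic) matrix W."""
        return self.W

    @property
    def log(self) -> pd.DataFrame:
        return self.train_log.to_frame()

    # -- evaluation ------------------------------------------------------
    def transfer(self) -> np.ndarray:
        """Source-to-output transfer K = W A (generative models only)."""
        if self.model.mixing is None:
            raise ValueError("transfer matrix requires a known mixing model")
        return self.W @ self.model.mixing.A

    def outputs_and_sources(self, n_samples: int = 100_000, seed: int = 0):
        """Fresh evaluation draw: returns (U, S, X).

        Generative models redraw n samples from the source distributions;
        image models evaluate every pixel column (n_samples ignored).
        """
        m = self.model
        if m.image_stream is not None:
            S = m.image_stream.S.T  # (n_pixels, M) centered source values
            X = m.image_stream.X.T
        else:
            rng = np.random.default_rng(seed)
            S = np.column_stack([sp.sample(n_samples, rng) for sp in m.source_specs])
            X = m.mixing.mix(S)
        return X @ self.W.T, S, X

    def match_report(self, n_samples: int = 100_000, seed: int = 0) -> _metrics.MetricReport:
        U, S, _ = self.outputs_and_sources(n_samples, seed)
        return _metrics.match_correlations(U, S)

    def costs(self, n_samples: int = 100_000, seed: int = 0, ica_samples: int = 20_000) -> dict:
        """Evaluate the cost functions on a fresh draw."""
        U, S, X = self.outputs_and_sources(n_samples, seed)
        total_var = None
        if self.model.mixing is not None:
            total_var = float(np.sum(self.model.mixing.eigenvalues))
        L, ica_term, pca_term = _metrics.eghr_cost(X, self.W, self.model.prior, self.model.beta)
        lx, lx_norm = _metrics.pca_cost(X, self.W, total_variance=total_var)
        la = _metrics.ica_cost(U[:ica_samples], self.model.prior)
        return {
            "eghr_cost": L, "ica_term": ica_term, "pca_term": pca_term,
            "pca_cost": lx, "pca_cost_normalized": lx_norm, "ica_cost": la,
        }

    def principal_angles(self, n_components: int | None = None) -> np.ndarray:
        """Principal angles (deg) between the transfer row space and the
        top principal-component subspace of the sources (B = I mixing)."""
        K = self.transfer()
        lam = self.model.mixing.eigenvalues
        r = n_components or self.model.n_outputs
        order = np.argsort(lam)[::-1][:r]
        ref = np.zeros((K.shape[1], r))
        ref[order, np.arange(r)] = 1.0
        return _metrics.subspace_angles(K, ref)

    # -- presentation ----------------------------------------------------
    def summary(self, n_samples: int = 50_000, seed: int = 0) -> str:
        """Plain-text summary of the run and its separation quality."""
        m = self.model
        buf = io.StringIO()
        w = buf.write
        w("Hebbian BSS results\n")
        w("=" * 60 + "\n")
        w(f"rule: {m.rule:<22} beta: {m.beta}\n")
        w(f"inputs: {m.n_inputs:<20} outputs: {m.n_outputs}\n")
        w(f"prior: {m.prior.family} (a={m.prior.a:g}, b={m.prior.b:.4g})\n")
        w(f"samples: {self.config.steps:<19} eta: {self.config.eta:g}\n")
        w(f"batch: {self.config.batch_size:<21} tau: {self.config.tau:g}\n")
        w(f"||W||_F: {np.linalg.norm(self.W):.4f}\n")
        try:
            costs = self.costs(n_samples=n_samples, seed=seed)
            w("-" * 60 + "\n")
            w(f"error-gated cost L: {costs['eghr_cost']:.4f} "
              f"(ICA {costs['ica_term']:.4f}, PCA {costs['pca_term']:.4f})\n")
            w(f"PCA cost (normalized): {costs['pca_cost_normalized']:.4f}\n")
            w(f"ICA cost D_KL[p(u)||p0(u)]: {costs['ica_cost']:.4f}\n")
        except Exception:
            pass
        rep = self.match_report(n_samples, seed)
        w("-" * 60 + "\n")
        w("output -> assigned source (|corr|):\n")
        for i in range(m.n_outputs):
            w(f"  u{i + 1} -> s{rep.assignment[i] + 1}  ({rep.assigned_corr[i]:.3f})\n")
        return buf.getvalue()

    def plot_outputs(self, n_samples: int = 10_000, seed: int = 0, path=None):
        """Scatter the final output distribution in (u1,u2) / (u3,u4) planes."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        U, _, _ = self.outputs_and_sources(n_samples, seed)
        U = U[:n_samples]
        n_pairs = U.shape[1] // 2
        fig, axes = plt.subplots(1, max(n_pairs, 1), figsize=(4 * max(n_pairs, 1), 4))
        axes = np.atleast_1d(axes)
        for p in range(n_pairs):
            ax = axes[p]
            ax.plot(U[:, 2 * p], U[:, 2 * p + 1], ".", ms=1, alpha=0.4)
            ax.set_xlabel(f"$u_{{{2 * p + 1}}}$")
            ax.set_ylabel(f"$u_{{{2 * p + 2}}}$")
            ax.set_aspect("equal")
        fig.suptitle(f"{self.model.rule} (beta={self.model.beta})")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig
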