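"""Cost functions and separation metrics.

Three costs quantify learning outcomes:

* the error-gated cost L (ICA + PCA terms, batch-mean expectations),
* the reconstruction (PCA) cost L_X = ⟨|x - Wᵀu|²⟩/2, optionally
  normalized by the total input variance Σ_i Λ_ii, and
* the ICA cost L_A = D_KL[p(u) || p0(u)], with the differential entropy of
  the outputs estimated nonparametrically (Kozachenko-Leonenko k-nearest-
  neighbour estimator) because no closed form exists for a trained
  undercomplete network.

Separation quality is measured by Pearson correlations between outputs and
sources: both the per-source best output (arg max_i |corr(u_i, s_j)|) and a
one-to-one assignment maximizing total |corr|, plus principal angles
between the learned transfer row space and a reference subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, spatial, special

from .priors import PriorSpec

__all__ = [
    "MetricReport",
    "eghr_cost",
    "pca_cost",
    "ica_cost",
    "kl_entropy",
    "match_correlations",
    "subspace_angles",
]


def eghr_cost(batch: np.ndarray, W: np.ndarray, prior: PriorSpec, beta: float):
    """Batch estimate of the error-gated cost.

    Returns ``(L, ica_term, pca_term)`` with expectations taken as batch
    means, so that the analytic update is the exact negated gradient of
    this quantity (checked by the gradient-oracle tests).
    """
    X = np.atleast_2d(np.asarray(batch, float))
    U = X @ W.T
    E = prior.energy(U)
    ica = float(np.mean(0.5 * (E - E.mean()) ** 2 - E))
    u2 = np.sum(U * U, axis=1)
    x2 = np.sum(X * X, axis=1)
    eu = 0.5 * (u2 - u2.mean())
    ex = 0.5 * (x2 - x2.mean())
    pca = float(np.mean(0.5 * (eu - ex) ** 2))
    return (1.0 - beta) * ica + beta * pca, ica, pca


def pca_cost(batch: np.ndarray, W: np.ndarray, total_variance: float | None = None):
    """Reconstruction cost L_X = ⟨|x - Wᵀu|²⟩/2 with u = W x.

    ``total_variance`` (the sum of eigenvalues of A Aᵀ when the mixing is
    known, else ⟨|x|²⟩) yields the normalized cost in [0, 1/2].
    Returns ``(L_X, normalized)``.
    """
    X = np.atleast_2d(np.asarray(batch, float))
    R = X - X @ W.T @ W
    lx = 0.5 * float(np.mean(np.sum(R * R, axis=1)))
    if total_variance is None:
        total_variance = float(np.mean(np.sum(X * X, axis=1)))
    return lx, lx / total_variance


def kl_entropy(X: np.ndarray, k: int = 3) -> float:
    """Kozachenko-Leonenko k-NN differential entropy estimate (nats).

    H ≈ ψ(n) - ψ(k) + log V_d + (d/n) Σ_i log ε_i with ε_i the distance
    from sample i to its k-th nearest neighbour and V_d the unit-ball
    volume.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, d = X.shape
    if n <= k:
        raise ValueError("need more samples than neighbours")
    tree = spatial.cKDTree(X)
    dist, _ = tree.query(X, k=k + 1, workers=-1)
    eps = np.clip(dist[:, -1], 1e-300, None)
    log_vd = (d / 2.0) * np.log(np.pi) - special.gammaln(d / 2.0 + 1.0)
    return float(special.digamma(n) - special.digamma(k) + log_vd + d * np.mean(np.log(eps)))


def ica_cost(outputs: np.ndarray, prior: PriorSpec, k: int = 3) -> float:
    """ICA cost L_A = D_KL[p(u) || p0(u)] = -H[p(u)] + ⟨-log p0(u)⟩.

    The output entropy is estimated with :func:`kl_entropy`; the prior
    cross term uses the smooth (surrogate) prior's normalized density.
    Requires at least 10³ samples for a usable entropy estimate.
    """
    U = np.atleast_2d(np.asarray(outputs, float))
    if U.shape[0] < 1000:
        raise ValueError(f"ica_cost needs >= 1000 samples, got {U.shape[0]}")
    return float(np.mean(prior.energy(U)) - kl_entropy(U, k=k))


@dataclass
class MetricReport:
    """Correlation-based matching between outputs and sources."""

    corr: np.ndarray               # (N outputs, M sources) |Pearson r|
    best_output: np.ndarray        # per source: arg max_i |corr|
    best_corr: np.ndarray          # per source: the max |corr|
    assignment: np.ndarray         # per output: assigned source (one-to-one)
    assigned_corr: np.ndarray      # per output: |corr| with its assigned source
    degenerate: np.ndarray         # mask of zero-variance channels (flagged)

    def to_frame(self) -> pd.DataFrame:
        M = self.corr.shape[1]
        return pd.DataFrame(
            {"source": np.arange(M), "best_output": self.best_output, "best_corr": self.best_corr}
        )


def match_correlations(outputs: np.ndarray, sources: np.ndarray) -> MetricReport:
    """|corr| matching table between output and source time series.

    Zero-variance channels are flagged and contribute correlation 0.  The
    one-to-one assignment maximizes the total |corr| over permutations
    (rectangular assignment), avoiding double counting when several
    sources are best described by the same output.
    """
    U = np.atleast_2d(np.asarray(outputs, float))
    S = np.atleast_2d(np.asarray(sources, float))
    if U.shape[0] != S.shape[0]:
        raise ValueError("outputs and sources need equal sample counts")
    Uc = U - U.mean(axis=0)
    Sc = S - S.mean(axis=0)
    su = np.sqrt(np.sum(Uc**2, axis=0))
    ss = np.sqrt(np.sum(Sc**2, axis=0))
    degenerate = (su == 0.0)
    denom = np.outer(np.where(degenerate, 1.0, su), np.where(ss == 0.0, 1.0, ss))
    corr = np.abs(Uc.T @ Sc) / denom
    corr[degenerate, :] = 0.0
    corr[:, ss == 0.0] = 0.0
    best_output = np.argmax(corr, axis=0)
    best_corr = corr[best_output, np.arange(corr.shape[1])]
    rows, cols = optimize.linear_sum_assignment(-corr)
    assignment = np.full(corr.shape[0], -1)
    assigned = np.zeros(corr.shape[0])
    assignment[rows] = cols
    assigned[rows] = corr[rows, cols]
    return MetricReport(corr, best_output, best_corr, assignment, assigned, degenerate)


def subspace_angles(K: np.ndarray, reference: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Principal angles between the row space of K and a reference subspace.

    ``reference`` holds basis vectors as columns (an (M, r) matrix).  A
    rank-deficient K is rejected (its row space is ill-defined at the
    requested dimension).
    """
    K = np.atleast_2d(np.asarray(K, float))
    if np.linalg.matrix_rank(K) < K.shape[0]:
        raise ValueError("K is rank deficient; row space undefined at full dimension")
    ang = linalg.subspace_angles(K.T, np.atleast_2d(np.asarray(reference, float)))
    ang = np.sort(ang)
    return np.degrees(ang) if degrees else ang
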