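"""Synthetic sources, mixing matrices, and image source sets.

A blind-source-separation instance is built from M independent hidden
sources s with zero mean and (usually) unit variance, mixed into inputs
x = A s by a square mixing matrix decomposed as ``A = R Λ^{1/2} B`` with
rotations R, B and a diagonal Λ.  The diagonal of Λ holds the eigenvalues
of A Aᵀ, i.e. the source variances as seen in input space.

The module also generates the image-demixing protocol's source material:
high-variance colored-noise images (truncated-Gaussian + Laplace pixel
mixture solved for mean 0.5, variance 0.023, excess kurtosis 0, upscaled
4x by pixel replication), low-variance uniform white-noise images
(mean 0.5, variance 0.002, excess kurtosis -1.2), and spatially structured
sub-Gaussian "natural image" stand-ins (variance 0.02, excess kurtosis
about -1).  User PNG images can replace the stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special, stats

__all__ = [
    "SourceSpec",
    "MixingModel",
    "ImageSourceSet",
    "MixedImageStream",
    "unit_variance_scale",
    "sample_sources",
    "make_rotation",
    "make_mixing",
    "make_image_sources",
    "mix_images",
    "load_png_sources",
    "solve_colored_noise_params",
]

_KNOWN_FAMILIES = ("gaussian", "uniform", "gen_gaussian", "laplace", "truncated_gaussian", "image")


def unit_variance_scale(a: float) -> float:
    """Scale b such that the density ∝ exp(-b|s|^a) has unit variance.

    Closed form b = (Γ(3/a) / Γ(1/a))^{a/2}; a = 2 gives 1/2 (unit
    Gaussian), a = 1 gives √2 (unit-variance Laplace).
    """
    if a <= 0:
        raise ValueError(f"shape exponent a must be positive, got {a}")
    return float((special.gamma(3.0 / a) / special.gamma(1.0 / a)) ** (a / 2.0))


@dataclass(frozen=True)
class SourceSpec:
    """One hidden source's distribution.

    Parameters
    ----------
    family : str
        ``gaussian | uniform | gen_gaussian | laplace | truncated_gaussian``.
    a, b : float, optional
        Generalized-Gaussian shape/scale (family ``gen_gaussian``); for
        ``truncated_gaussian``, ``b`` is the pre-truncation standard
        deviation.  If ``b`` is omitted for ``gen_gaussian`` it is tuned so
        the variance matches ``variance``.
    mean, variance : float
        First two moments of the source.
    low, high : float, optional
        Truncation bounds (``truncated_gaussian`` only).
    """

    family: str = "gaussian"
    a: float | None = None
    b: float | None = None
    mean: float = 0.0
    variance: float = 1.0
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.family not in _KNOWN_FAMILIES:
            raise ValueError(f"unknown source family {self.family!r}; expected one of {_KNOWN_FAMILIES}")
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.family == "gen_gaussian":
            if self.a is None or self.a <= 0:
                raise ValueError("gen_gaussian requires shape exponent a > 0")
            if self.b is None:
                # b for the requested variance: unit-variance scale shrunk by v^{a/2}
                object.__setattr__(self, "b", unit_variance_scale(self.a) * self.variance ** (-self.a / 2.0))
        if self.family == "truncated_gaussian":
            if self.b is None or self.b <= 0:
                raise ValueError("truncated_gaussian requires pre-truncation std b > 0")
            if self.low is None or self.high is None:
                raise ValueError("truncated_gaussian requires low/high bounds")

    # ------------------------------------------------------------------
    @property
    def dist(self):
        """Frozen scipy distribution implementing the spec."""
        f = self.family
        if f == "gaussian":
            return stats.norm(loc=self.mean, scale=np.sqrt(self.variance))
        if f == "uniform":
            h = np.sqrt(3.0 * self.variance)
            return stats.uniform(loc=self.mean - h, scale=2.0 * h)
        if f == "gen_gaussian":
            return stats.gennorm(self.a, loc=self.mean, scale=self.b ** (-1.0 / self.a))
        if f == "laplace":
            return stats.laplace(loc=self.mean, scale=np.sqrt(self.variance / 2.0))
        if f == "truncated_gaussian":
            alpha = (self.low - self.mean) / self.b
            beta = (self.high - self.mean) / self.b
            return stats.truncnorm(alpha, beta, loc=self.mean, scale=self.b)
        raise ValueError(f"family {f!r} has no scalar distribution")

    @property
    def kurtosis(self) -> float:
        """Excess kurtosis ⟨(s-μ)^4⟩/var² - 3 of the family."""
        if self.family == "gaussian":
            return 0.0
        if self.family == "uniform":
            return -1.2
        if self.family == "laplace":
            return 3.0
        if self.family == "gen_gaussian":
            a = self.a
            return float(
                special.gamma(5.0 / a) * special.gamma(1.0 / a) / special.gamma(3.0 / a) ** 2 - 3.0
            )
        return float(self.dist.stats(moments="k"))

    @property
    def actual_variance(self) -> float:
        """Variance implied by the distribution (equals ``variance`` except
        for truncated_gaussian, whose ``b`` is the pre-truncation std)."""
        return float(self.dist.stats(moments="v"))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError(f"sample count must be >= 1, got {n}")
        # direct Generator paths (the scipy rvs machinery is too slow for
        # the per-batch draws of an online training run)
        if self.family == "gaussian":
            return rng.normal(self.mean, np.sqrt(self.variance), size=n)
        if self.family == "uniform":
            h = np.sqrt(3.0 * self.variance)
            return rng.uniform(self.mean - h, self.mean + h, size=n)
        if self.family == "laplace":
            return rng.laplace(self.mean, np.sqrt(self.variance / 2.0), size=n)
        if self.family == "gen_gaussian":
            # |s - mean| = (t/b)^{1/a} with t ~ Gamma(1/a, 1), random sign
            t = rng.gamma(1.0 / self.a, 1.0, size=n)
            mag = (t / self.b) ** (1.0 / self.a)
            return self.mean + np.where(rng.random(n) < 0.5, mag, -mag)
        if self.family == "truncated_gaussian":
            # rejection sampling: draw the parent Gaussian, keep in-bounds draws
            out = np.empty(n)
            have = 0
            while have < n:
                need = n - have
                cand = rng.normal(self.mean, self.b, size=int(need * 1.2) + 8)
                cand = cand[(cand >= self.low) & (cand <= self.high)]
                take = min(need, cand.size)
                out[have : have + take] = cand[:take]
                have += take
            return out
        return self.dist.rvs(size=n, random_state=rng)

    def pdf(self, s):
        return self.dist.pdf(s)


def sample_sources(specs: list[SourceSpec], n: int, seed) -> np.ndarray:
    """Draw an (n, M) matrix whose column i follows specs[i], independently."""
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return np.column_stack([spec.sample(n, rng) for spec in specs])


# ---------------------------------------------------------------------------
# mixing
# ---------------------------------------------------------------------------

def make_rotation(dim: int, seed) -> np.ndarray:
    """Haar-distributed rotation (orthogonal, det +1)."""
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    if dim == 1:
        return np.ones((1, 1))
    rng = np.random.default_rng(seed)
    return stats.special_ortho_group.rvs(dim, random_state=rng)


@dataclass(frozen=True)
class MixingModel:
    """Mixing matrix A = R Λ^{1/2} B with its rotation/eigenvalue factors."""

    R: np.ndarray
    eigenvalues: np.ndarray  # diag(Λ): eigenvalues of A Aᵀ
    B: np.ndarray
    A: np.ndarray = field(init=False)

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        B = np.asarray(self.B, dtype=float)
        lam = np.asarray(self.eigenvalues, dtype=float)
        if R.shape != B.shape or R.shape[0] != R.shape[1] or lam.shape != (R.shape[0],):
            raise ValueError("R, B must be square and match len(eigenvalues)")
        if np.any(lam < 0):
            raise ValueError("eigenvalues must be non-negative")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "A", R @ np.diag(np.sqrt(lam)) @ B)

    @property
    def M(self) -> int:
        return self.A.shape[0]

    def mix(self, S: np.ndarray) -> np.ndarray:
        """Map an (n, M) source matrix to inputs X = S Aᵀ (rows are samples)."""
        return S @ self.A.T


def make_mixing(R: np.ndarray, eigenvalues, B: np.ndarray | None = None) -> MixingModel:
    """Assemble A = R Λ^{1/2} B (B defaults to the identity)."""
    R = np.asarray(R, dtype=float)
    if B is None:
        B = np.eye(R.shape[0])
    return MixingModel(R=R, eigenvalues=np.asarray(eigenvalues, dtype=float), B=np.asarray(B, float))


# ---------------------------------------------------------------------------
# image sources
# ---------------------------------------------------------------------------

def solve_colored_noise_params(variance: float = 0.023, kurtosis: float = 0.0):
    """Solve the colored-noise pixel model for its two free parameters.

    A colored-noise pixel is X + Y with X a Gaussian of mean 0.5 truncated
    to [0, 1] (pre-truncation std sigma) and Y an independent Laplace of
    scale ell.  Truncation makes X platykurtic, Laplace is leptokurtic
    (excess +3); sigma and ell are chosen so the sum has the target variance
    and excess kurtosis.  Returns ``(sigma, ell)``.
    """
    if not -2.0 < kurtosis < 3.0:
        raise ValueError("target kurtosis must lie strictly between the mixture extremes (-2, 3)")

    def trunc_moments(sigma):
        alpha, beta = -0.5 / sigma, 0.5 / sigma
        v, k = stats.truncnorm.stats(alpha, beta, scale=sigma, moments="vk")
        return float(v), float(k)

    def total_var(sigma):
        vt, kt = trunc_moments(sigma)
        # for given sigma, the Laplace variance solving the kurtosis target:
        # kt*vt^2 + 3*vl^2 = kurtosis*(vt+vl)^2
        def kurt_resid(vl):
            return kt * vt**2 + 3.0 * vl**2 - kurtosis * (vt + vl) ** 2
        if kurt_resid(0.0) > 0:  # already too heavy-tailed
            return vt
        vl = optimize.brentq(kurt_resid, 0.0, 10.0 * vt + 1.0)
        return vt + vl

    try:
        sigma = optimize.brentq(lambda s: total_var(s) - variance, 1e-3, 0.6)
    except ValueError as exc:  # pragma: no cover - diagnostic path
        raise ArithmeticError(
            f"colored-noise moment constraints (var={variance}, kurt={kurtosis}) "
            f"are not solvable by the truncated-Gaussian + Laplace mixture"
        ) from exc
    vt, kt = trunc_moments(sigma)
    vl = total_var(sigma) - vt
    ell = float(np.sqrt(vl / 2.0))
    return float(sigma), ell


def _solve_tanh_gain(target_kurt: float) -> float:
    """Gain c such that tanh(c Z), Z ~ N(0,1), has the target excess kurtosis.

    c → 0 gives 0 (Gaussian); c → ∞ gives −2 (binary).  Solved by Gauss-
    Hermite quadrature + bisection.
    """
    z, w = np.polynomial.hermite_e.hermegauss(201)
    w = w / w.sum()

    def kurt(c):
        y = np.tanh(c * z)
        m2 = np.sum(w * y**2)
        m4 = np.sum(w * y**4)
        return m4 / m2**2 - 3.0

    return float(optimize.brentq(lambda c: kurt(c) - target_kurt, 1e-3, 50.0))


@dataclass
class ImageSourceSet:
    """A stack of image sources on a constant 0.5 gray background.

    ``images`` has shape (M, H, W, 3) with intensities around 0.5;
    ``labels`` tags each image ``colored_noise | natural_standin |
    white_noise`` (or ``png``).
    """

    images: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must have shape (M, H, W, 3)")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError("one label per image required")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.images.shape[1:]))

    def as_matrix(self, centered: bool = True) -> np.ndarray:
        """(M, H*W*3) matrix of pixel vectors; centered subtracts the
        constant 0.5 background (the protocol's mean removal)."""
        S = self.images.reshape(self.n_images, -1)
        return S - 0.5 if centered else S

    def statistics(self) -> pd.DataFrame:
        """Per-image mean/variance/excess kurtosis."""
        S = self.as_matrix(centered=False)
        return pd.DataFrame(
            {
                "label": self.labels,
                "mean": S.mean(axis=1),
                "variance": S.var(axis=1),
                "kurtosis": stats.kurtosis(S, axis=1, fisher=True),
            }
        )


def _colored_noise_images(n, size, upscale, variance, kurtosis, rng):
    if size % upscale:
        raise ValueError(f"image size {size} must be divisible by the upscale factor {upscale}")
    base = size // upscale
    sigma, ell = solve_colored_noise_params(variance, kurtosis)
    spec = SourceSpec("truncated_gaussian", b=sigma, mean=0.5, low=0.0, high=1.0)
    out = np.empty((n, size, size, 3))
    for i in range(n):
        px = spec.sample(base * base * 3, rng) + rng.laplace(0.0, ell, size=base * base * 3)
        small = px.reshape(base, base, 3)
        out[i] = np.repeat(np.repeat(small, upscale, axis=0), upscale, axis=1)
    return out


def _white_noise_images(n, size, variance, rng):
    h = np.sqrt(3.0 * variance)
    return rng.uniform(0.5 - h, 0.5 + h, size=(n, size, size, 3))


def _natural_standin_images(n, size, variance, kurtosis, smooth, corr, rng):
    """Sub-Gaussian spatially structured stand-ins for natural images.

    A Gaussian random field (white noise smoothed over ``smooth`` pixels)
    is squashed through tanh with the gain solved so the marginal excess
    kurtosis hits the target, then rescaled to the target variance around
    the 0.5 background.  The stand-ins share a common structure component
    giving pairwise pixel correlation about ``corr`` — like several
    photographs of related subjects.  At the default corr the unit-norm
    mixture of the four stand-ins has variance just above the colored-noise
    level, making it the (barely) leading principal component of the
    demixing benchmark; this is what defeats the PCA-then-ICA cascade.
    """
    c = _solve_tanh_gain(kurtosis)
    base = rng.standard_normal((size, size, 3))
    out = np.empty((n, size, size, 3))
    for i in range(n):
        z = np.sqrt(corr) * base + np.sqrt(1.0 - corr) * rng.standard_normal((size, size, 3))
        z = ndimage.gaussian_filter(z, sigma=(smooth, smooth, 0), mode="wrap")
        z = (z - z.mean()) / z.std()
        y = np.tanh(c * z)
        y = (y - y.mean()) / y.std() * np.sqrt(variance)
        out[i] = 0.5 + y
    return out


def make_image_sources(
    n_colored: int = 12,
    n_natural: int = 4,
    n_white: int = 84,
    size: int = 48,
    upscale: int = 4,
    colored_var: float = 0.023,
    colored_kurt: float = 0.0,
    white_var: float = 0.002,
    natural_var: float = 0.02,
    natural_kurt: float = -1.0,
    natural_smooth: float = 3.0,
    natural_corr: float = 0.15,
    seed=None,
    natural_pngs: list | None = None,
) -> ImageSourceSet:
    """Generate the image-demixing source set.

    Defaults follow the demixing protocol scaled to 48x48 images: 12
    high-variance colored-noise images (variance 0.023, excess kurtosis 0),
    4 sub-Gaussian natural-image stand-ins (variance 0.02, excess kurtosis
    about -1), and 84 low-variance uniform white-noise images (variance
    0.002, excess kurtosis -1.2).  ``natural_pngs`` substitutes user PNG
    files (rescaled to [0,1] and adjusted to ``natural_var``) for the
    stand-ins.
    """
    if min(n_colored, n_natural, n_white) < 0:
        raise ValueError("image counts must be non-negative")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    if n_colored:
        blocks.append(_colored_noise_images(n_colored, size, upscale, colored_var, colored_kurt, rng))
        labels += ["colored_noise"] * n_colored
    if n_natural:
        if natural_pngs is not None:
            nat = load_png_sources(natural_pngs, size=size, target_var=natural_var)
            if nat.shape[0] != n_natural:
                raise ValueError("number of PNG files must match n_natural")
            blocks.append(nat)
        else:
            blocks.append(
                _natural_standin_images(n_natural, size, natural_var, natural_kurt,
                                        natural_smooth, natural_corr, rng)
            )
        labels += ["natural_standin"] * n_natural
    if n_white:
        blocks.append(_white_noise_images(n_white, size, white_var, rng))
        labels += ["white_noise"] * n_white
    return ImageSourceSet(images=np.concatenate(blocks, axis=0), labels=labels)


def load_png_sources(paths, size: int | None = None, target_var: float = 0.02) -> np.ndarray:
    """Load PNG files as image sources: RGB in [0,1], mean moved to 0.5,
    pixel variance adjusted to ``target_var``."""
    from PIL import Image

    out = []
    for p in paths:
        try:
            img = Image.open(Path(p)).convert("RGB")
        except Exception as exc:
            raise IOError(f"cannot read PNG source {p!r}: {exc}") from exc
        if size is not None:
            img = img.resize((size, size), Image.NEAREST)
        arr = np.asarray(img, dtype=float) / 255.0
        dev = arr - arr.mean()
        arr = 0.5 + dev * np.sqrt(target_var / dev.var())
        out.append(arr)
    return np.stack(out)


class MixedImageStream:
    """Stream of mixed pixel vectors x = R s_col.

    A column of the centered source-pixel matrix (all M sources at one
    (pixel, channel) position) is drawn uniformly with replacement and
    rotated into input space.
    """

    def __init__(self, images: ImageSourceSet, R: np.ndarray, seed=None):
        R = np.asarray(R, dtype=float)
        if R.shape != (images.n_images, images.n_images):
            raise ValueError(
                f"rotation is {R.shape} but there are {images.n_images} image sources"
            )
        self.images = images
        self.R = R
        self.rng = np.random.default_rng(seed)
        self.S = images.as_matrix(centered=True)  # (M, n_pixels)
        self.X = R @ self.S  # premixed, (M, n_pixels)

    @property
    def dim(self) -> int:
        return self.R.shape[0]

    def sample(self, n: int) -> np.ndarray:
        """(n, M) batch of mixed pixel vectors."""
        idx = self.rng.integers(0, self.S.shape[1], size=n)
        return self.X[:, idx].T

    def __iter__(self):
        while True:
            yield self.sample(1)[0]


def mix_images(images: ImageSourceSet, R: np.ndarray, seed=None) -> MixedImageStream:
    """Create the seeded stream of rotated pixel-column samples."""
    return MixedImageStream(images, R, seed=seed)
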