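"""Shift-invariant kernels and their random Fourier feature approximations.

One kernel is built per feature group.  For a shift-invariant kernel
k(x, y) = k(x - y), Bochner's theorem gives k(Δ) = E_ω[cos(ωᵀΔ)] with ω
drawn from the kernel's spectral density p(ω); the feature map

    z(x) = sqrt(1/D) [cos(ω₁ᵀx) … cos(ω_Dᵀx)  sin(ω₁ᵀx) … sin(ω_Dᵀx)]

satisfies E[z(x)·z(y)] = k(x, y), so an N × 2D matrix Z replaces the
N × N kernel matrix and kernel-method cost drops from quadratic to
linear in cells.

Kernels (width s > 0):

* gaussian:   k(Δ) = exp(-‖Δ‖₂² / s²)      ω_d ~ Normal(0, 2/s²)
* laplacian:  k(Δ) = exp(-‖Δ‖₁ / s)        ω_d ~ Cauchy(0, 1/s)
* cauchy:     k(Δ) = ∏_d 1/(1+(Δ_d/s)²)    ω_d ~ Laplace(0, 1/s)

Spectral-law derivation for the gaussian: exp(-δ²/s²) is the
characteristic function of N(0, 2/s²) evaluated at δ, since
E[e^{iωδ}] = exp(-σ²δ²/2) with σ² = 2/s².  The laplacian/cauchy pair
follow from the Cauchy↔Laplace Fourier duality: the characteristic
function of Cauchy(0, b) is exp(-b|δ|) (b = 1/s), and that of
Laplace(0, b) is 1/(1 + b²δ²).

The width is set by a data heuristic: the mean pairwise distance
(euclidean for the gaussian, L1 for laplacian/cauchy) over a subsample
of at most 2000 training cells and 200 of the group's features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist

logger = logging.getLogger("cellmkl")

KERNELS = ("gaussian", "laplacian", "cauchy")


@dataclass
class KernelConfig:
    kernel: str
    width: float
    D: int
    seed: object = 0

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; expected one of {KERNELS}")
        if not self.width > 0:
            raise ValueError("kernel width must be > 0")
        if self.D < 1:
            raise ValueError("D must be >= 1")


@dataclass
class RFFBasis:
    """Sampled frequency matrix W (group_dim × D) plus its configuration.

    Row order of W is bound to ``feature_ids``: the matrix a basis is
    applied to must present the group's features in exactly this order.
    """

    W: np.ndarray
    config: KernelConfig
    feature_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("frequency matrix contains non-finite values")
        if self.W.shape[1] != self.config.D:
            raise ValueError(f"W has {self.W.shape[1]} columns but config.D = {self.config.D}")


def kernel_eval(kernel, s, u, v):
    """Evaluate one kernel at a pair of vectors; k(u, u) = 1 for all three."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if not s > 0:
        raise ValueError("width s must be > 0")
    d = u - v
    if kernel == "gaussian":
        return float(np.exp(-np.dot(d, d) / s**2))
    if kernel == "laplacian":
        return float(np.exp(-np.abs(d).sum() / s))
    if kernel == "cauchy":
        return float(np.prod(1.0 / (1.0 + (d / s) ** 2)))
    raise ValueError(f"unknown kernel {kernel!r}")


def kernel_matrix(kernel, s, X, Y=None):
    """Exact pairwise kernel matrix; the oracle the RFF map approximates."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if kernel == "gaussian":
        sq = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
        return np.exp(-sq / s**2)
    if kernel == "laplacian":
        l1 = np.abs(X[:, None, :] - Y[None, :, :]).sum(-1)
        return np.exp(-l1 / s)
    if kernel == "cauchy":
        return np.prod(1.0 / (1.0 + ((X[:, None, :] - Y[None, :, :]) / s) ** 2), axis=-1)
    raise ValueError(f"unknown kernel {kernel!r}")


def _metric_for(kernel):
    return "euclidean" if kernel == "gaussian" else "cityblock"


def estimate_width(x_group, kernel="gaussian", n_cells=2000, n_features=200, seed=0):
    """Kernel-width heuristic: mean pairwise distance on a training subsample.

    Subsamples min(n_cells, N) cells and min(n_features, |G|) of the
    group's features without replacement, then averages the distance
    matched to the kernel (euclidean for gaussian, L1 for
    laplacian/cauchy) over all unordered pairs.  Degenerate data (all
    distances zero) falls back to s = 1 with a warning.
    """
    v = x_group.toarray() if sp.issparse(x_group) else np.asarray(x_group, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    n, p = v.shape
    if n < 2:
        raise ValueError("need at least 2 cells to estimate a kernel width")
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=min(n_cells, n), replace=False) if n > n_cells else np.arange(n)
    cols = rng.choice(p, size=min(n_features, p), replace=False) if p > n_features else np.arange(p)
    sub = v[np.ix_(rows, cols)]
    s = float(pdist(sub, metric=_metric_for(kernel)).mean())
    if s == 0.0:
        logger.warning("degenerate data (all pairwise distances zero); width fallback s = 1")
        s = 1.0
    return s


def default_D(n_train):
    """Default number of random frequencies: ceil(sqrt(N) · ln(ln N)).

    This is the scaling at which the RFF approximation error of the kernel
    matrix becomes negligible for N training cells.  Requires N ≥ 16 so
    that ln(ln N) is defined and positive; below that, pass D explicitly.
    """
    n_train = int(n_train)
    if n_train < 16:
        raise ValueError(
            f"default_D undefined for n_train = {n_train} < 16; specify D explicitly"
        )
    return int(math.ceil(math.sqrt(n_train) * math.log(math.log(n_train))))


def sample_frequencies(config, group_dim, feature_ids=None):
    """Draw D i.i.d. frequency vectors from the kernel's spectral density."""
    if group_dim < 1:
        raise ValueError("group_dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    s, D = config.width, config.D
    if config.kernel == "gaussian":
        W = rng.normal(0.0, math.sqrt(2.0) / s, size=(group_dim, D))
    elif config.kernel == "laplacian":
        W = rng.standard_cauchy(size=(group_dim, D)) / s
    elif config.kernel == "cauchy":
        W = rng.laplace(0.0, 1.0 / s, size=(group_dim, D))
    else:  # unreachable: KernelConfig validates
        raise ValueError(f"unknown kernel {config.kernel!r}")
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(group_dim)]
    if len(feature_ids) != group_dim:
        raise ValueError("feature_ids length must equal group_dim")
    return RFFBasis(W, config, list(feature_ids))


def compute_z(x_group, basis, feature_ids=None):
    """Apply the RFF map: Z = sqrt(1/D) [cos(XW) | sin(XW)], shape N × 2D.

    Row norms are exactly 1 (cos² + sin² summed over D frequencies), and
    Z_i · Z_j is an unbiased Monte-Carlo estimate of k(x_i, x_j).
    ``feature_ids``, when given, is checked against the basis row order.
    """
    v = x_group.toarray() if sp.issparse(x_group) else np.asarray(x_group, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[1] != basis.W.shape[0]:
        raise ValueError(
            f"matrix has {v.shape[1]} features but basis expects {basis.W.shape[0]}"
        )
    if feature_ids is not None and list(feature_ids) != list(basis.feature_ids):
        raise ValueError("feature order does not match the basis feature order")
    proj = v @ basis.W
    scale = math.sqrt(1.0 / basis.config.D)
    return scale * np.hstack([np.cos(proj), np.sin(proj)])


DEFAULT_KERNEL_BY_MODALITY = {"RNA": "gaussian", "GAS": "gaussian", "ATAC": "laplacian"}


def default_kernel(modality, atac_scheme="binary"):
    """Per-modality default: gaussian for RNA/GAS and TF-IDF ATAC,
    laplacian for binary ATAC (sparser solutions on presence/absence data)."""
    if modality == "ATAC" and atac_scheme == "tfidf":
        return "gaussian"
    return DEFAULT_KERNEL_BY_MODALITY[modality]
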