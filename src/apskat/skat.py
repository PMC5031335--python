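"""SKAT core: variant weights, the quadratic-form statistic, and its asymptotic p-value.

The statistic for a set of m variants is

    s = z' G W G' z,        z = y - mu,

with G the n x m dosage matrix and W = diag(w_1..w_m) non-negative variant
weights.  It is computed as ||V'z||^2 with V = G diag(sqrt(w)); V is cached on
the returned object because the permutation engine reuses it for every
permuted z.

Under the null, s is distributed as a mixture sum(lambda_i * chi2_1) whose
mixture weights are the eigenvalues of the null-covariance-weighted kernel:
for quantitative traits sigma^2 * eig(V'(I-H)V) with H the covariate hat
matrix, and for binary traits the analogous form with diag(mu(1-mu)) in place
of sigma^2 I.  Two tail evaluators are provided: a three-moment match to a
noncentral chi-square (default, fast) and exact numerical inversion of the
characteristic function (Imhof-type quadrature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .exceptions import DimensionError
from .io import GenotypeMatrix
from .null_model import NullModelFit

logger = logging.getLogger("apskat")

EIGEN_RTOL = 1e-10  # eigenvalues below EIGEN_RTOL * lambda_max are discarded


@dataclass
class SkatStatistic:
    """Observed statistic plus the cached transformed genotypes V = G diag(sqrt(w))."""

    s: float
    transformed: np.ndarray  # n x m


def beta_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density variant weights evaluated at the MAF.

    ``w_j = Beta(maf_j; a, b)`` with the SKAT-conventional default Beta(1, 25),
    which up-weights rare variants steeply; ``a = b = 1`` gives flat weights.
    MAF must be strictly positive (filter monomorphic variants first).
    """
    maf = np.asarray(maf, dtype=float)
    if a <= 0 or b <= 0:
        raise ValueError("Beta shape parameters must be positive")
    if np.any(~(maf > 0.0)):
        raise ValueError("beta_weights requires maf > 0 for every variant; "
                         "remove monomorphic variants first")
    return stats.beta.pdf(maf, a, b)


def skat_statistic(z: np.ndarray,
                   g: GenotypeMatrix | np.ndarray,
                   weights: np.ndarray) -> SkatStatistic:
    """Compute s = z' G W G' z = ||V'z||^2 and cache V for permutation reuse.

    Missing dosages are mean-imputed on the fly when ``g`` is a
    :class:`GenotypeMatrix`; a plain array is used as-is.
    """
    G = g.imputed() if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    z = np.asarray(z, dtype=float)
    w = np.asarray(weights, dtype=float)
    if G.shape[0] != z.size or G.shape[1] != w.size:
        raise DimensionError(f"shape mismatch: G {G.shape}, z {z.size}, w {w.size}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    V = G * np.sqrt(w)
    u = V.T @ z
    return SkatStatistic(s=float(u @ u), transformed=V)


def kernel_eigenvalues(V: np.ndarray, fit: NullModelFit, rtol: float = EIGEN_RTOL) -> np.ndarray:
    """Eigenvalues of the null-covariance-weighted kernel.

    Quantitative: sigma^2 * eig(V'(I-H)V); binary: eig(U'(I-H_d)U) with
    U = sqrt(D)V, D = diag(mu(1-mu)) and H_d the D-weighted hat matrix.  The
    Gram matrix is formed on the smaller side (m x m when m < n).  Eigenvalues
    below ``rtol * lambda_max`` are discarded.
    """
    X = fit.design
    if fit.trait_type == "quantitative":
        A = V - X @ np.linalg.lstsq(X, V, rcond=None)[0]
        scale = fit.sigma2
    else:
        d = np.sqrt(fit.mu * (1.0 - fit.mu))
        U = V * d[:, None]
        Xd = X * d[:, None]
        A = U - Xd @ np.linalg.lstsq(Xd, U, rcond=None)[0]
        scale = 1.0
    n, m = A.shape
    gram = A.T @ A if m <= n else A @ A.T
    lam = np.linalg.eigvalsh(gram)
    lam = lam[lam > max(lam[-1], 0.0) * rtol] if lam.size else lam
    return scale * lam[::-1]


def _liu_sf(q: float | np.ndarray, lam: np.ndarray) -> float | np.ndarray:
    """Upper-tail probability of sum(lam_i chi2_1) by the modified three-moment
    match to a (noncentral) chi-square."""
    c1 = lam.sum()
    c2 = (lam ** 2).sum()
    c3 = (lam ** 3).sum()
    c4 = (lam ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2.0 * delta
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        delta = 0.0
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * a
    t = (np.asarray(q, dtype=float) - c1) / np.sqrt(2.0 * c2)
    x = t * sigma_x + mu_x
    if delta > 0:
        p = stats.ncx2.sf(x, df, delta)
    else:
        p = stats.chi2.sf(x, df)
    return p if np.ndim(q) else float(p)


def _imhof_sf(q: float, lam: np.ndarray, limit: int = 200) -> float:
    """Exact upper-tail probability by numerical inversion of the
    characteristic function (Imhof's integral).

    The integrand sin(theta(u))/(u rho(u)) oscillates at frequency q/2 for
    large u, so it is split as sin(phi)cos(qu/2) - cos(phi)sin(qu/2) with
    phi(u) = sum(atan(lam u))/2 and each half is integrated with
    Fourier-weighted quadrature, which sums the oscillation tail to
    convergence.  One eigenvalue is a plain scaled chi-square.
    """
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))

    def envelope(u: float) -> float:
        # 1/(u * rho(u)); rho on the log scale to avoid overflow
        return float(np.exp(-0.25 * np.log1p((lam * u) ** 2).sum()) / u)

    def smooth_sin(u: float) -> float:
        return math.sin(0.5 * np.arctan(lam * u).sum()) * envelope(u)

    def smooth_cos(u: float) -> float:
        return math.cos(0.5 * np.arctan(lam * u).sum()) * envelope(u)

    def integrand(u: float) -> float:
        theta = 0.5 * np.arctan(lam * u).sum() - 0.5 * q * u
        return math.sin(theta) * envelope(u)

    omega = 0.5 * q
    # [0, eps] is non-oscillatory (and removes the 1/u split singularity);
    # beyond eps, Fourier-weighted quadrature sums the oscillation tail
    eps = 0.1 / max(omega, math.sqrt((lam ** 2).sum()))
    head, _ = integrate.quad(integrand, 0.0, eps, limit=limit)
    i1, _ = integrate.quad(smooth_sin, eps, np.inf, weight="cos", wvar=omega,
                           limit=limit)
    i2, _ = integrate.quad(smooth_cos, eps, np.inf, weight="sin", wvar=omega,
                           limit=limit)
    val = head + i1 - i2
    return float(min(1.0, max(0.0, 0.5 + val / np.pi)))


def asymptotic_pvalue(stat: SkatStatistic, fit: NullModelFit,
                      method: str = "liu") -> float:
    """Mixture-of-chi-squares upper-tail p-value for the observed statistic.

    ``method`` is ``"liu"`` (three-moment match; default) or ``"imhof"``
    (exact characteristic-function inversion).  A degenerate kernel (all
    eigenvalues ~ 0) yields p = 1 with a warning.
    """
    lam = kernel_eigenvalues(stat.transformed, fit)
    if lam.size == 0 or lam[0] <= 0:
        logger.warning("degenerate kernel: all eigenvalues ~ 0; returning p = 1")
        return 1.0
    if stat.s <= 0:
        return 1.0
    if method == "liu":
        p = _liu_sf(stat.s, lam)
    elif method == "imhof":
        p = _imhof_sf(stat.s, lam)
    else:
        raise ValueError(f"unknown method {method!r}; use 'liu' or 'imhof'")
    return float(min(1.0, max(0.0, p)))
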