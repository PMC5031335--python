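"""Null-model fitting: intercept(+covariate) regression with no genotype terms.

The set-association statistic is a quadratic form in the residuals z = y - mu,
where mu are the predicted means under "no association": an ordinary
least-squares fit for quantitative traits and a maximum-likelihood logistic
fit for case/control traits.  Permutation of z is scale-free in the statistic,
so the residual variance estimate is needed only by the asymptotic p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .exceptions import CollinearityError, ConvergenceError, DimensionError
from .io import PhenotypeData


@dataclass
class NullModelFit:
    """Fitted null means and residuals.

    Attributes
    ----------
    mu : predicted means under the null (length n).
    residuals : z = y - mu.
    trait_type : "quantitative" or "binary".
    sigma2 : unbiased residual variance RSS/(n-k-1); None for binary traits.
    design : the n x (k+1) design matrix (intercept first), kept for the
        covariate projection in the asymptotic p-value.
    """

    mu: np.ndarray
    residuals: np.ndarray
    trait_type: str
    sigma2: float | None
    design: np.ndarray

    @property
    def n(self) -> int:
        return self.mu.size

    @property
    def n_covariates(self) -> int:
        return self.design.shape[1] - 1


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR on the scaled design
        _, r, piv = scipy.linalg.qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if i >= rank or diag[i] < tol]
        raise CollinearityError(f"design matrix is rank deficient (rank {rank} of "
                                f"{X.shape[1]}); collinear column(s): {bad}")


def fit_null(pheno: PhenotypeData) -> NullModelFit:
    """Fit the no-association null model and return means and residuals.

    Quantitative traits use OLS on intercept + covariates; binary traits use a
    maximum-likelihood logistic regression.  A logistic fit that separates
    (fitted probabilities pinned to 0/1) raises :class:`ConvergenceError`.
    """
    y = pheno.values
    n = y.size
    k = 0 if pheno.covariates is None else pheno.covariates.shape[1]
    if n < k + 2:
        raise DimensionError(f"need at least k+2={k + 2} samples, got {n}")
    X = np.ones((n, 1)) if k == 0 else np.column_stack([np.ones(n), pheno.covariates])
    names = ["intercept"] + (pheno.covariate_names or [])[:k]
    _check_design(X, names)

    if pheno.trait_type == "quantitative":
        fit = sm.OLS(y, X).fit()
        mu = np.asarray(fit.fittedvalues)
        resid = y - mu
        dof = n - k - 1
        sigma2 = float(resid @ resid / dof)
        return NullModelFit(mu=mu, residuals=resid, trait_type="quantitative",
                            sigma2=sigma2, design=X)

    # binary
    classes = np.unique(y)
    if classes.size < 2:
        raise ConvergenceError("binary trait has a single class; the null "
                               "prevalence model is degenerate")
    try:
        with warnings.catch_warnings():
            # separation surfaces as a warning in recent statsmodels; treat it
            # as the failure it is
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise ConvergenceError(
            f"logistic null fit failed ({exc}); check for separation between "
            "covariates and case status, or drop the offending covariate") from exc
    mu = np.asarray(fit.predict(X))
    eps = 1e-10
    if np.any(mu <= eps) or np.any(mu >= 1 - eps):
        raise ConvergenceError("logistic null fit produced probabilities at 0/1 "
                               "(quasi-separation); drop the offending covariate")
    return NullModelFit(mu=mu, residuals=y - mu, trait_type="binary",
                        sigma2=None, design=X)
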