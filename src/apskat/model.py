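"""Single-set modelling interface: ``SkatModel.fit() -> SkatResults``.

This is the front door for testing one SNP set against one phenotype.  The
model holds the data and the analysis choices (trait type, variant weights,
MAF filter); ``fit()`` fits the null regression, computes the quadratic-form
statistic and returns a results object from which the asymptotic p-value,
the adaptive permutation p-value and a summary table are available.

Example
-------
>>> model = SkatModel(pheno, genotypes)          # doctest: +SKIP
>>> res = model.fit()                            # doctest: +SKIP
>>> res.asymptotic_pvalue()                      # doctest: +SKIP
>>> res.permutation_test(alpha_e=0.05, b=10_000) # doctest: +SKIP
>>> print(res.summary())                         # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adaptive import PermutationResult, StoppingConfig, adaptive_pvalue, set_rng
from .exceptions import ConfigurationError
from .io import GenotypeMatrix, PhenotypeData, filter_rare
from .null_model import NullModelFit, fit_null
from .skat import SkatStatistic, asymptotic_pvalue, beta_weights, skat_statistic


class SkatModel:
    """A SKAT set-association model for one SNP set.

    Parameters
    ----------
    phenotype
        :class:`~apskat.io.PhenotypeData` (quantitative or binary, optional
        covariates), sample-aligned with the genotypes.
    genotypes
        :class:`~apskat.io.GenotypeMatrix` for the variants of the set.
    weights
        ``("beta", a, b)`` for Beta-density weights at the MAF (default
        Beta(1, 25)), ``"flat"`` for unit weights, or an explicit array.
    maf_threshold
        Strict upper MAF bound for the rare-variant filter; ``None`` disables
        filtering.
    """

    def __init__(self, phenotype: PhenotypeData, genotypes: GenotypeMatrix,
                 weights="beta", maf_threshold: float | None = 0.05):
        if phenotype.n != genotypes.n:
            raise ConfigurationError("phenotype and genotype sample counts differ; "
                                     "align samples first")
        self.phenotype = phenotype
        self.genotypes = genotypes
        self.weights = weights
        self.maf_threshold = maf_threshold

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, phenotype: str,
                       covariates: list[str] | None = None,
                       variants: list[str] | None = None,
                       trait_type: str = "quantitative",
                       **kwargs) -> "SkatModel":
        """Build a model from one DataFrame holding trait, covariate and
        dosage columns; ``variants`` defaults to every column not otherwise
        claimed."""
        covariates = list(covariates or [])
        if variants is None:
            variants = [c for c in data.columns
                        if c != phenotype and c not in covariates]
        pheno = PhenotypeData(
            values=data[phenotype].to_numpy(dtype=float),
            sample_ids=[str(i) for i in data.index],
            covariates=data[covariates].to_numpy(dtype=float) if covariates else None,
            covariate_names=covariates or None,
            trait_type=trait_type,
        )
        geno = GenotypeMatrix(
            dosages=data[variants].to_numpy(dtype=float),
            sample_ids=[str(i) for i in data.index],
            variant_ids=list(variants),
        )
        return cls(pheno, geno, **kwargs)

    def _resolve_weights(self, g: GenotypeMatrix) -> np.ndarray:
        w = self.weights
        if isinstance(w, str):
            if w == "beta":
                return beta_weights(g.maf)
            if w == "flat":
                return np.ones(g.m)
            raise ConfigurationError(f"unknown weight spec {w!r}")
        if isinstance(w, tuple) and w and w[0] == "beta":
            return beta_weights(g.maf, *w[1:])
        arr = np.asarray(w, dtype=float)
        if arr.size != g.m:
            raise ConfigurationError("explicit weights length does not match the "
                                     "filtered variant count")
        return arr

    def fit(self) -> "SkatResults":
        """Fit the null model, filter and weight variants, compute the statistic."""
        null_fit = fit_null(self.phenotype)
        g = self.genotypes
        if self.maf_threshold is not None:
            g = filter_rare(g, self.maf_threshold)
        if g.m == 0:
            raise ConfigurationError("no polymorphic variants left after the MAF "
                                     "filter; nothing to test")
        w = self._resolve_weights(g)
        stat = skat_statistic(null_fit.residuals, g, w)
        return SkatResults(self, null_fit, g, w, stat)


class SkatResults:
    """Results of :meth:`SkatModel.fit`.

    Carries the fitted null model, the filtered genotypes, the weights and
    the observed statistic; p-values are computed lazily on request.
    """

    def __init__(self, model: SkatModel, null_fit: NullModelFit,
                 genotypes: GenotypeMatrix, weights: np.ndarray,
                 stat: SkatStatistic):
        self.model = model
        self.null_fit = null_fit
        self.genotypes = genotypes
        self.weights = weights
        self.stat = stat
        self._p_asym: dict[str, float] = {}
        self.permutation_result: PermutationResult | None = None

    @property
    def statistic(self) -> float:
        return self.stat.s

    def asymptotic_pvalue(self, method: str = "liu") -> float:
        """Mixture-of-chi-squares p-value (``"liu"`` moment match or ``"imhof"``)."""
        if method not in self._p_asym:
            self._p_asym[method] = asymptotic_pvalue(self.stat, self.null_fit,
                                                     method=method)
        return self._p_asym[method]

    def permutation_test(self, config: StoppingConfig | None = None,
                         **kwargs) -> PermutationResult:
        """Adaptive permutation p-value; keyword arguments build a
        :class:`StoppingConfig` when none is given."""
        cfg = config if config is not None else StoppingConfig(**kwargs)
        self.permutation_result = adaptive_pvalue(
            self.null_fit.residuals, self.stat.transformed, self.stat.s, cfg,
            set_rng(cfg.seed, 0))
        return self.permutation_result

    def summary(self) -> str:
        """Human-readable summary of the fit and any computed p-values."""
        lines = [
            "SKAT set-association results",
            "=" * 44,
            f"{'trait type':<28}{self.null_fit.trait_type}",
            f"{'samples (n)':<28}{self.null_fit.n}",
            f"{'covariates (k)':<28}{self.null_fit.n_covariates}",
            f"{'variants tested (m)':<28}{self.genotypes.m}",
            f"{'statistic s':<28}{self.statistic:.6g}",
        ]
        for method, p in self._p_asym.items():
            lines.append(f"{'asymptotic p (' + method + ')':<28}{p:.4g}")
        pr = self.permutation_result
        if pr is not None:
            lines += [
                f"{'permutation p_hat':<28}{pr.p_hat:.4g}",
                f"{'permutations B':<28}{pr.B}",
                f"{'exceedances r':<28}{pr.r}",
                f"{'stop reason':<28}{pr.stop_reason}",
            ]
        lines.append("=" * 44)
        return "\n".join(lines)
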