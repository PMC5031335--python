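"""Adaptive permutation engine: early-stopping p-value estimation and the genome scan.

The permutation p-value of a set statistic s is p_hat = r/B, where r counts
permutation statistics strictly greater than s after B permutations.  Rather
than always running a fixed budget b (which must be at least 1/alpha_p to
resolve the Bonferroni per-set threshold alpha_p = alpha_e / m_sets), the
engine draws permutations in batches of M and stops as soon as the decision
is settled:

* 0 < r < B: stop when the normal-approximation confidence interval
  p_hat +/- z_{1-alpha/2} sqrt(p_hat(1-p_hat)/B) excludes alpha_p
  ("ci_exclusion"); the CI tail mass alpha is a tunable (recommended:
  alpha = alpha_p).
* r = 0: the binomial variance vanishes, so a negative-binomial criterion
  applies: stop when (1-alpha_p)^B < alpha_p, reporting p_hat = 1/B
  ("nb_zero").
* r = B: stop when alpha_e^B < alpha_p, reporting p_hat = 1 ("nb_all").
* otherwise run to the budget b ("max_reached"); with r = 0 at the budget the
  estimate is the resolution floor 1/b.

"Refine" mode ignores any stop with p_hat < alpha_p and continues to b, so
significant sets get the sharpest available estimate (down to 1/b).

Per-set random substreams are derived from (seed, set index), making scan
results identical under any execution order or worker count.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .io import GenotypeMatrix, PhenotypeData, SnpSetCollection, filter_rare
from .null_model import NullModelFit, fit_null
from .skat import asymptotic_pvalue, beta_weights, skat_statistic

logger = logging.getLogger("apskat")


def minimum_permutations(alpha_e: float, m_sets: int) -> int:
    """Smallest permutation budget that can resolve the per-set threshold.

    With alpha_p = alpha_e / m_sets, a p-value of alpha_p is only reachable
    after 1/alpha_p permutations, so b must be at least ceil(m_sets/alpha_e).
    """
    if not 0 < alpha_e <= 1:
        raise ConfigurationError(f"alpha_e must lie in (0, 1], got {alpha_e}")
    if m_sets < 1:
        raise ConfigurationError(f"m_sets must be >= 1, got {m_sets}")
    return math.ceil(m_sets / alpha_e)


def recommended_permutations(alpha_e: float, m_sets: int) -> int:
    """The recommended budget b = 5/alpha_p (five times the minimum)."""
    return 5 * minimum_permutations(alpha_e, m_sets)


@dataclass
class StoppingConfig:
    """Parameters of the adaptive engine.

    Attributes
    ----------
    alpha_e : genome-wide significance level.
    m_sets : number of SNP sets tested (1 for a single-set analysis).
    ci_level : tail mass alpha of the stopping confidence interval
        (coverage 1 - alpha); defaults to alpha_p.
    b : maximum number of permutations; defaults to 5/alpha_p and must be at
        least 1/alpha_p.
    batch : permutations drawn between stop-rule checks (M); default 1000.
    refine : continue to b whenever a stop would report p_hat < alpha_p.
    seed : master seed for the per-set substreams.
    """

    alpha_e: float = 0.05
    m_sets: int = 1
    ci_level: float | None = None
    b: int | None = None
    batch: int = 1000
    refine: bool = False
    seed: int = 0
    alpha_p: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.alpha_e <= 1:
            raise ConfigurationError(f"alpha_e must lie in (0, 1], got {self.alpha_e}")
        if self.m_sets < 1:
            raise ConfigurationError(f"m_sets must be >= 1, got {self.m_sets}")
        self.alpha_p = self.alpha_e / self.m_sets
        if self.ci_level is None:
            self.ci_level = self.alpha_p
        if not 0 < self.ci_level < 1:
            raise ConfigurationError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if self.b is None:
            self.b = recommended_permutations(self.alpha_e, self.m_sets)
        min_b = minimum_permutations(self.alpha_e, self.m_sets)
        if self.b < min_b:
            raise ConfigurationError(
                f"b={self.b} cannot resolve alpha_p={self.alpha_p:g}; "
                f"need at least {min_b} permutations")
        if self.batch < 1:
            raise ConfigurationError(f"batch must be >= 1, got {self.batch}")


@dataclass
class PermutationResult:
    """Outcome of one adaptive permutation run."""

    p_hat: float
    B: int
    r: int
    stop_reason: str  # ci_exclusion | nb_zero | nb_all | max_reached
    ci_halfwidth: float  # NaN when r in {0, B}


# ---------------------------------------------------------------------------
# Stop rules
# ---------------------------------------------------------------------------

def ci_halfwidth(p_hat: float, B: int, ci_level: float) -> float:
    """Half of d_alpha: z_{1-alpha/2} * sqrt(p_hat(1-p_hat)/B).

    Undefined at p_hat in {0, 1} (zero binomial variance; the
    negative-binomial rules apply there instead).
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError("ci_halfwidth requires 0 < p_hat < 1; "
                         "use the negative-binomial rules at the boundary")
    if B < 1:
        raise ValueError("B must be >= 1")
    z = stats.norm.ppf(1.0 - ci_level / 2.0)
    return float(z * math.sqrt(p_hat * (1.0 - p_hat) / B))


def ci_stop(p_hat: float, B: int, cfg: StoppingConfig) -> bool:
    """True iff alpha_p lies outside [p_hat - d/2, p_hat + d/2]."""
    half = ci_halfwidth(p_hat, B, cfg.ci_level)
    return cfg.alpha_p < p_hat - half or cfg.alpha_p > p_hat + half


def nb_zero_stop(B: int, alpha_p: float) -> bool:
    """r = 0 rule: stop once (1 - alpha_p)^B < alpha_p (then p_hat = 1/B).

    If the true p-value were as large as alpha_p, observing zero exceedances
    in B permutations would itself be an event rarer than alpha_p.
    """
    return B * math.log1p(-alpha_p) < math.log(alpha_p)


def nb_all_stop(B: int, alpha_e: float, alpha_p: float) -> bool:
    """r = B rule: stop once alpha_e^B < alpha_p (then p_hat = 1)."""
    if alpha_e >= 1.0:
        return False
    return B * math.log(alpha_e) < math.log(alpha_p)


def first_nb_zero_B(alpha_p: float) -> int:
    """Smallest B at which :func:`nb_zero_stop` fires."""
    B = int(math.ceil(math.log(alpha_p) / math.log1p(-alpha_p)))
    while not nb_zero_stop(B, alpha_p):
        B += 1
    while B > 1 and nb_zero_stop(B - 1, alpha_p):
        B -= 1
    return B


def first_nb_all_B(alpha_e: float, alpha_p: float) -> int:
    """Smallest B at which :func:`nb_all_stop` fires."""
    if alpha_e >= 1.0:
        raise ValueError("nb_all_stop never fires for alpha_e = 1")
    B = max(1, int(math.ceil(math.log(alpha_p) / math.log(alpha_e))))
    while not nb_all_stop(B, alpha_e, alpha_p):
        B += 1
    while B > 1 and nb_all_stop(B - 1, alpha_e, alpha_p):
        B -= 1
    return B


# ---------------------------------------------------------------------------
# Permutation mechanics
# ---------------------------------------------------------------------------

def permutation_statistics(z: np.ndarray, V: np.ndarray, count: int,
                           rng: np.random.Generator) -> np.ndarray:
    """``count`` statistics ||V' pi(z)||^2 for independent uniform permutations pi."""
    Z = rng.permuted(np.tile(z, (count, 1)), axis=1)
    S = Z @ V
    return np.einsum("ij,ij->i", S, S)


def adaptive_pvalue(z: np.ndarray, V: np.ndarray, s: float,
                    cfg: StoppingConfig,
                    rng: np.random.Generator) -> PermutationResult:
    """Run the adaptive permutation loop for one set.

    Draws batches of ``cfg.batch`` permutation statistics, counting strict
    exceedances r of the observed s, and checks (in order) the r = 0
    negative-binomial rule, the r = B rule, and the CI-exclusion rule after
    each batch.  See the module docstring for the estimate conventions.
    """
    B = 0
    r = 0
    b = cfg.b
    while B < b:
        m_eff = min(cfg.batch, b - B)
        batch_stats = permutation_statistics(z, V, m_eff, rng)
        r += int((batch_stats > s).sum())
        B += m_eff

        stop_reason = None
        p_hat = None
        if r == 0:
            if nb_zero_stop(B, cfg.alpha_p):
                stop_reason, p_hat = "nb_zero", 1.0 / B
        elif r == B:
            if nb_all_stop(B, cfg.alpha_e, cfg.alpha_p):
                stop_reason, p_hat = "nb_all", 1.0
        else:
            if ci_stop(r / B, B, cfg):
                stop_reason, p_hat = "ci_exclusion", r / B
        if stop_reason is not None:
            if cfg.refine and p_hat < cfg.alpha_p:
                continue  # sharpen significant sets all the way to b
            half = ci_halfwidth(r / B, B, cfg.ci_level) if 0 < r < B else math.nan
            return PermutationResult(p_hat=p_hat, B=B, r=r,
                                     stop_reason=stop_reason, ci_halfwidth=half)

    p_hat = r / B if r > 0 else 1.0 / B
    half = ci_halfwidth(r / B, B, cfg.ci_level) if 0 < r < B else math.nan
    return PermutationResult(p_hat=p_hat, B=B, r=r,
                             stop_reason="max_reached", ci_halfwidth=half)


def standard_pvalue(z: np.ndarray, V: np.ndarray, s: float, b: int,
                    rng: np.random.Generator,
                    batch: int = 10_000) -> PermutationResult:
    """Fixed-budget permutation p-value (the standard procedure): always B = b."""
    r = 0
    done = 0
    while done < b:
        m_eff = min(batch, b - done)
        r += int((permutation_statistics(z, V, m_eff, rng) > s).sum())
        done += m_eff
    p_hat = r / b if r > 0 else 1.0 / b
    half = ci_halfwidth(r / b, b, 0.05) if 0 < r < b else math.nan
    return PermutationResult(p_hat=p_hat, B=b, r=r,
                             stop_reason="max_reached", ci_halfwidth=half)


def set_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-set substream: results never depend on execution order."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

SCAN_COLUMNS = ["set_id", "n_variants_raw", "n_variants_rare", "statistic",
                "p_asymptotic", "p_hat", "B", "r", "stop_reason", "status"]


def _scan_one(set_id: str, idx: np.ndarray, g: GenotypeMatrix, fit: NullModelFit,
              cfg: StoppingConfig, set_index: int, maf_threshold: float,
              weight_params: tuple[float, float] | None,
              compute_asymptotic: bool) -> dict:
    row = {c: None for c in SCAN_COLUMNS}
    row["set_id"] = set_id
    row["n_variants_raw"] = int(idx.size)
    sub = g.subset_variants(idx)
    rare = filter_rare(sub, maf_threshold)
    row["n_variants_rare"] = rare.m
    if rare.m == 0:
        row["status"] = "skipped"
        logger.info("set %s skipped: no polymorphic variant below MAF %.3g",
                    set_id, maf_threshold)
        return row
    if weight_params is None:
        w = np.ones(rare.m)
    else:
        w = beta_weights(rare.maf, *weight_params)
    stat = skat_statistic(fit.residuals, rare, w)
    row["statistic"] = stat.s
    if compute_asymptotic:
        row["p_asymptotic"] = asymptotic_pvalue(stat, fit)
    res = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                          set_rng(cfg.seed, set_index))
    row.update(p_hat=res.p_hat, B=res.B, r=res.r, stop_reason=res.stop_reason,
               status="ok")
    return row


def genome_scan(g: GenotypeMatrix, sets: SnpSetCollection, pheno: PhenotypeData,
                cfg: StoppingConfig, *, maf_threshold: float = 0.05,
                weight_params: tuple[float, float] | None = (1.0, 25.0),
                compute_asymptotic: bool = True,
                threads: int = 1) -> pd.DataFrame:
    """Test every SNP set and return one row per set.

    The null model is fitted once; each set is MAF-filtered, weighted,
    tested adaptively on its own (seed, set-index) substream, and reported
    with its statistic, optional asymptotic p-value, p_hat, B, r and stop
    reason.  ``threads`` distributes sets over a worker pool without changing
    any result.
    """
    fit = fit_null(pheno)
    if fit.n != g.n:
        raise ConfigurationError("genotype and phenotype sample counts differ; "
                                 "align samples first")
    resolved = sets.resolve(g)
    jobs = [(set_id, idx, i) for i, (set_id, idx) in enumerate(resolved.items())]

    def run(job):
        set_id, idx, i = job
        return _scan_one(set_id, idx, g, fit, cfg, i, maf_threshold,
                         weight_params, compute_asymptotic)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            rows = list(pool.map(run, jobs))
    else:
        rows = [run(job) for job in jobs]
    table = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    counts = table["stop_reason"].value_counts().to_dict()
    total_B = int(pd.to_numeric(table["B"], errors="coerce").fillna(0).sum())
    logger.info("scan complete: %d sets, stop reasons %s, total permutations %d",
                len(table), counts, total_B)
    return table
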