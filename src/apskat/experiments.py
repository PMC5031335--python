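"""Evaluation protocols: power/sample-size grids, heavy-tailed type-I error
counts, and the standard-vs-adaptive agreement comparison.

All experiments run on the synthetic panel of :mod:`apskat.synthetic`.  Power
cells are per-test rejection rates of single-set analyses (alpha_p = alpha,
no multiplicity), the type-I protocol counts sets declared significant at the
Bonferroni per-set threshold across whole-scan experiments with Student-t(5)
noise, and the comparison protocol contrasts the fixed-budget permutation
estimate with the adaptive one over a grid of CI levels — reporting
permutation counts rather than wall-clock time, which is hardware-dependent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .adaptive import (StoppingConfig, adaptive_pvalue, minimum_permutations,
                       set_rng, standard_pvalue)
from .exceptions import ConfigurationError
from .io import GenotypeMatrix, PhenotypeData, filter_rare
from .null_model import fit_null
from .skat import asymptotic_pvalue, beta_weights, skat_statistic
from .synthetic import (HaplotypePanel, SimulationConfig, assign_effects,
                        draw_genotypes, generate_panel, sample_region,
                        simulate_dataset, simulate_phenotype)

logger = logging.getLogger("apskat")

METHODS = ("asymptotic_skat", "ap_skat")


def _single_set_pvalues(panel: HaplotypePanel, sim: SimulationConfig,
                        methods: tuple[str, ...], alphas: list[float],
                        rng: np.random.Generator, b_factor: int = 5,
                        ) -> dict[tuple[str, float], float] | None:
    """One replicate: simulate a region, test it, return p per (method, alpha).

    Returns None when the sampled region has no rare variant (caller logs and
    resamples)."""
    region = sample_region(panel, sim.region_length, rng)
    genotypes = draw_genotypes(panel=region, n=sim.n, rng=rng)
    panel_maf = np.minimum(region.frequencies, 1.0 - region.frequencies)
    if not np.any((panel_maf > 0) & (panel_maf < sim.maf_threshold)):
        return None
    beta = assign_effects(panel_maf, sim, rng)
    pheno = simulate_phenotype(genotypes, beta, sim, rng)
    rare = filter_rare(genotypes, sim.maf_threshold)
    if rare.m == 0:
        return None
    fit = fit_null(pheno)
    stat = skat_statistic(fit.residuals, rare, beta_weights(rare.maf))
    out: dict[tuple[str, float], float] = {}
    if "asymptotic_skat" in methods:
        p = asymptotic_pvalue(stat, fit)
        for alpha in alphas:
            out[("asymptotic_skat", alpha)] = p
    if "ap_skat" in methods:
        for alpha in alphas:
            cfg = StoppingConfig(alpha_e=alpha, m_sets=1,
                                 b=b_factor * math.ceil(1 / alpha),
                                 seed=int(rng.integers(2 ** 31)))
            res = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                                  set_rng(cfg.seed, 0))
            out[("ap_skat", alpha)] = res.p_hat
    return out


def power_experiment(panel: HaplotypePanel, sim: SimulationConfig,
                     methods: tuple[str, ...] = METHODS,
                     alphas: list[float] = (1e-2, 1e-3, 1e-4),
                     sizes: list[int] = (250, 500, 750, 1000, 1250, 1500),
                     replicates: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Estimated power per sample size, significance level and method.

    Each replicate samples a fresh 5-kb region, assigns effects to 20 % of its
    rare variants, simulates the trait and runs each method as a single-set
    test (alpha_p = alpha, b = 5/alpha).  Cells are the fraction of
    replicates with p <= alpha, with the binomial Monte-Carlo standard error.
    """
    rows = []
    for n in sizes:
        sim_n = replace(sim, n=n)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(n,)))
        hits = {key: 0 for key in ((m, a) for m in methods for a in alphas)}
        done = 0
        resampled = 0
        while done < replicates:
            pvals = _single_set_pvalues(panel, sim_n, methods, list(alphas), rng)
            if pvals is None:
                resampled += 1
                if resampled > 50 * replicates:
                    raise RuntimeError("too many regions without rare variants")
                continue
            for (method, alpha), p in pvals.items():
                hits[(method, alpha)] += p <= alpha
            done += 1
        if resampled:
            logger.info("n=%d: resampled %d region(s) without rare variants",
                        n, resampled)
        for method in methods:
            for alpha in alphas:
                power = hits[(method, alpha)] / replicates
                rows.append({
                    "n": n, "alpha": alpha, "method": method, "power": power,
                    "replicates": replicates,
                    "se": math.sqrt(power * (1 - power) / replicates),
                })
    return pd.DataFrame(rows)


def required_sample_size(table: pd.DataFrame, target: float = 0.8) -> pd.DataFrame:
    """Smallest grid sample size reaching the target power per (alpha, method).

    Grid points are scanned in increasing n; a column that never reaches the
    target reports ``NaN`` (beyond the grid).
    """
    rows = []
    for (alpha, method), grp in table.groupby(["alpha", "method"]):
        grp = grp.sort_values("n")
        reached = grp.loc[grp["power"] >= target, "n"]
        rows.append({"alpha": alpha, "method": method, "target": target,
                     "n_required": float(reached.iloc[0]) if len(reached) else math.nan})
    return pd.DataFrame(rows)


def type1_experiment(panel: HaplotypePanel, sim: SimulationConfig,
                     n_sets: int = 20, n_experiments: int = 20,
                     alpha_e: float = 0.05, seed: int = 0,
                     noise: str = "student_t_df5") -> pd.DataFrame:
    """False-positive counts of the asymptotic and adaptive tests under the null.

    Each experiment simulates a whole cohort with ``n_sets`` random regions,
    all effects zero and heavy-tailed (Student-t, 5 df) noise, scans every set
    with both methods and counts sets declared significant at the Bonferroni
    per-set threshold alpha_p = alpha_e / n_sets.  Totals are summed across
    experiments.
    """
    null_sim = replace(sim, causal_fraction=0.0, noise=noise)
    alpha_p = alpha_e / n_sets
    counts = {m: 0 for m in METHODS}
    total_sets = 0
    for exp in range(n_experiments):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(exp,)))
        genotypes, sets, pheno = simulate_dataset(panel, null_sim, n_sets,
                                                  causal_set_fraction=0.0, rng=rng)
        fit = fit_null(pheno)
        resolved = sets.resolve(genotypes)
        for i, (set_id, idx) in enumerate(resolved.items()):
            rare = filter_rare(genotypes.subset_variants(idx), null_sim.maf_threshold)
            if rare.m == 0:
                continue
            total_sets += 1
            stat = skat_statistic(fit.residuals, rare, beta_weights(rare.maf))
            if asymptotic_pvalue(stat, fit) <= alpha_p:
                counts["asymptotic_skat"] += 1
            cfg = StoppingConfig(alpha_e=alpha_e, m_sets=n_sets,
                                 seed=int(rng.integers(2 ** 31)))
            res = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                                  set_rng(cfg.seed, i))
            if res.p_hat <= alpha_p:
                counts["ap_skat"] += 1
    return pd.DataFrame([
        {"method": m, "false_positives": counts[m], "sets_tested": total_sets,
         "alpha_p": alpha_p, "n": null_sim.n, "noise": noise}
        for m in METHODS
    ])


def null_calibration(panel: HaplotypePanel, sim: SimulationConfig,
                     replicates: int = 2000, alpha: float = 0.05,
                     b: int = 1000, seed: int = 0) -> dict[str, float]:
    """Empirical type-I error of both tests on single null sets.

    Per replicate: a fresh 5-kb region, Gaussian phenotypes independent of the
    genotypes, and a single-set test at level ``alpha``.  The permutation
    budget ``b`` defaults to 1000 rather than the scan default 5/alpha so the
    p-value resolution (rejection probability (floor(alpha*b)+1)/(b+1) under a
    uniform null) does not visibly inflate the measured rate.
    """
    null_sim = replace(sim, causal_fraction=0.0, noise="gaussian")
    rng = np.random.default_rng(seed)
    hits = {"asymptotic_skat": 0, "ap_skat": 0}
    done = 0
    while done < replicates:
        region = sample_region(panel, null_sim.region_length, rng)
        genotypes = draw_genotypes(panel=region, n=null_sim.n, rng=rng)
        pheno = simulate_phenotype(genotypes, np.zeros(genotypes.m), null_sim, rng)
        rare = filter_rare(genotypes, null_sim.maf_threshold)
        if rare.m == 0:
            continue
        fit = fit_null(pheno)
        stat = skat_statistic(fit.residuals, rare, beta_weights(rare.maf))
        hits["asymptotic_skat"] += asymptotic_pvalue(stat, fit) <= alpha
        cfg = StoppingConfig(alpha_e=alpha, m_sets=1, b=b, batch=b,
                             seed=int(rng.integers(2 ** 31)))
        res = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                              set_rng(cfg.seed, 0))
        hits["ap_skat"] += res.p_hat <= alpha
        done += 1
    return {"rate_asymptotic": hits["asymptotic_skat"] / replicates,
            "rate_adaptive": hits["ap_skat"] / replicates,
            "replicates": replicates}


def comparison_dataset(seed: int = 0, n_sets: int = 200, n: int = 250,
                       causal_set_fraction: float = 0.15,
                       max_effect: float = 1.2,
                       panel_haplotypes: int = 2000, panel_sites: int = 1500):
    """The fixed synthetic cohort used for standard-vs-adaptive comparisons:
    a scaled panel, 200 random 5-kb sets, 15 % of them carrying effects so the
    set p-values span the whole scale."""
    panel = generate_panel(H=panel_haplotypes, S=panel_sites,
                           region_length=200_000, seed=seed)
    sim = SimulationConfig(n=n, max_effect=max_effect, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(99,)))
    return simulate_dataset(panel, sim, n_sets, causal_set_fraction, rng)


def compare_standard_adaptive(genotypes: GenotypeMatrix, sets, pheno: PhenotypeData,
                              alpha_e: float = 0.05, b: int = 100_000,
                              ci_levels: list[float] = (0.05, 2.5e-6, 2.5e-11),
                              maf_threshold: float = 0.05,
                              seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contrast fixed-budget and adaptive permutation estimates per CI level.

    For every testable set the standard procedure runs exactly ``b``
    permutations; the adaptive procedure (refine mode, recommended batching)
    is replayed on the same per-set permutation stream at each CI level, so
    differences across levels are attributable to the stopping rule alone.
    Returns (per-set table, per-CI-level summary).  The summary's agreement
    metric is max |log10(p_hat/p_standard)| over sets whose adaptive estimate
    is above the resolution floor 1/b; total permutation counts stand in for
    run time.
    """
    fit = fit_null(pheno)
    resolved = sets.resolve(genotypes)
    rows = []
    for i, (set_id, idx) in enumerate(resolved.items()):
        rare = filter_rare(genotypes.subset_variants(idx), maf_threshold)
        if rare.m == 0:
            continue
        stat = skat_statistic(fit.residuals, rare, beta_weights(rare.maf))
        std = standard_pvalue(fit.residuals, stat.transformed, stat.s, b,
                              set_rng(seed, 2 * i + 1))
        row = {"set_id": set_id, "statistic": stat.s, "p_standard": std.p_hat,
               "r_standard": std.r}
        for ci in ci_levels:
            cfg = StoppingConfig(alpha_e=alpha_e, m_sets=len(resolved),
                                 ci_level=ci, b=b, refine=True, seed=seed)
            res = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                                  set_rng(seed, 2 * i))
            row[f"p_hat[{ci:g}]"] = res.p_hat
            row[f"B[{ci:g}]"] = res.B
        rows.append(row)
    table = pd.DataFrame(rows)

    summary_rows = []
    for ci in ci_levels:
        p_hat = table[f"p_hat[{ci:g}]"]
        above_floor = p_hat > 1.0 / b
        ratio = np.abs(np.log10(p_hat[above_floor] / table.loc[above_floor,
                                                               "p_standard"]))
        total_B = int(table[f"B[{ci:g}]"].sum())
        summary_rows.append({
            "ci_level": ci,
            "max_abs_log10_ratio": float(ratio.max()) if len(ratio) else math.nan,
            "total_adaptive_permutations": total_B,
            "total_standard_permutations": int(b * len(table)),
            "permutation_fraction": total_B / (b * len(table)),
        })
    return table, pd.DataFrame(summary_rows)


def compare_grid(genotypes: GenotypeMatrix, sets, pheno: PhenotypeData,
                 b_grid: list[int], ci_levels: list[float] = (0.05, 2.5e-6, 2.5e-11),
                 alpha_e: float = 0.05, maf_threshold: float = 0.05,
                 seed: int = 0) -> pd.DataFrame:
    """Run :func:`compare_standard_adaptive` over a grid of permutation budgets.

    Budgets below the resolution floor 1/alpha_p cannot classify a set at the
    per-set threshold and are skipped with a logged note.  Returns the stacked
    per-(b, ci) summary table.
    """
    resolved = sets.resolve(genotypes)
    min_b = minimum_permutations(alpha_e, len(resolved))
    frames = []
    for b in b_grid:
        if b < min_b:
            logger.info("skipping b=%d: below the resolution floor 1/alpha_p=%d",
                        b, min_b)
            continue
        _, summary = compare_standard_adaptive(
            genotypes, sets, pheno, alpha_e=alpha_e, b=b, ci_levels=ci_levels,
            maf_threshold=maf_threshold, seed=seed)
        summary.insert(0, "b", b)
        frames.append(summary)
    if not frames:
        raise ConfigurationError(
            f"every budget in {list(b_grid)} is below the floor {min_b}")
    return pd.concat(frames, ignore_index=True)
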