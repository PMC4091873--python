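"""Monte-Carlo calibration studies for the statistical pipeline.

Each study re-runs a pipeline component on freshly simulated data with known
truth and summarises its operating characteristics: type-I error and
confidence-interval coverage of the per-feature GEE, calibration and power
of the variance-heterogeneity likelihood-ratio test, agreement of the
permutation enrichment p-value with the exact hypergeometric tail, the
exactness of the parsimony pathway solver against exhaustive search, and
agreement of Monte-Carlo rarefaction with the analytic expectation.

All studies are deterministic given their seed and sized to run on a single
CPU in a few minutes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .diffabund import fit_feature_gee
from .diversity import expected_rarefied_richness, fit_diversity_model, rarefy
from .enrichment import hypergeometric_tail, permutation_enrichment
from .profiles import minimal_pathway_set
from .simulate import SimulationConfig, generate_counts, generate_design
from .tables import CountTable, PathwayMembership


def _seed_stream(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def gee_null_type1(
    n_reps: int = 200,
    n_features_fit: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the GEE diet test on null data at nominal ``alpha``.

    Each replicate simulates the 12-kitten x 3-week design with no diet
    effect and tests ``n_features_fit`` common features.
    """
    seeds = _seed_stream(seed, n_reps)
    rep_rates = []
    for s in seeds:
        cfg = SimulationConfig(
            n_features=20,
            base_abundance_logsigma=0.5,
            prop_features_affected=0.0,
            diet_effect_log_or=0.0,
            seed=s,
        )
        design = generate_design(cfg)
        table, _ = generate_counts(cfg, design)
        rejections = []
        for fid in table.feature_ids[:n_features_fit]:
            res = fit_feature_gee(
                table.counts.loc[fid], table.annotated_total, design, critical_p=alpha
            )
            if res.converged:
                rejections.append(res.wald_p["diet"] < alpha)
        if rejections:
            rep_rates.append(np.mean(rejections))
    rates = np.asarray(rep_rates)
    return {
        "rate": float(rates.mean()),
        "se": float(rates.std(ddof=1) / math.sqrt(len(rates))),
        "n_reps": len(rates),
    }


def gee_coverage(
    n_reps: int = 200,
    log_or: float = math.log(2),
    seed: int = 0,
) -> dict:
    """95% Wald CI coverage of a planted diet log odds ratio.

    One common feature per replicate carries the planted effect; because
    the generator is multinomial-logit, a single-feature shift is exactly
    the feature's marginal log odds ratio.
    """
    seeds = _seed_stream(seed, n_reps)
    covered, bias = [], []
    for s in seeds:
        cfg = SimulationConfig(
            n_features=30,
            base_abundance_logsigma=0.5,
            prop_features_affected=1 / 30,
            diet_effect_log_or=log_or,
            seed=s,
        )
        design = generate_design(cfg)
        table, truth = generate_counts(cfg, design)
        fid = truth.affected_features[0]
        true_val = float(truth.diet_log_or[fid])
        res = fit_feature_gee(
            table.counts.loc[fid], table.annotated_total, design, critical_p=0.05
        )
        if not res.converged:
            continue
        lo, hi = np.log(res.ci95[0]), np.log(res.ci95[1])
        covered.append(lo <= true_val <= hi)
        bias.append(res.beta_diet - true_val)
    cov = np.asarray(covered, dtype=float)
    return {
        "coverage": float(cov.mean()),
        "se": float(cov.std(ddof=1) / math.sqrt(len(cov))),
        "mean_bias": float(np.mean(bias)),
        "bias_mc_se": float(np.std(bias, ddof=1) / math.sqrt(len(bias))),
        "n_reps": len(cov),
    }


def _simulate_shannon(rng, design, sigma_hplc, sigma_mpmc, tau=0.15):
    kit_fx = {k: rng.normal(0, tau) for k in design["kitten"].unique()}
    sig = np.where(design["diet"] == "HPLC", sigma_hplc, sigma_mpmc)
    y = 3.5 + np.array([kit_fx[k] for k in design["kitten"]]) + rng.normal(0, sig)
    return pd.DataFrame({"H": y}, index=design.index)


def lrt_null_calibration(n_reps: int = 500, alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the variance-heterogeneity LRT under equal variances."""
    design = generate_design(SimulationConfig())
    seeds = _seed_stream(seed, n_reps)
    rejections = []
    for s in seeds:
        rng = np.random.default_rng(s)
        rec = _simulate_shannon(rng, design, 0.12, 0.12)
        fit = fit_diversity_model(rec, design)
        rejections.append(fit.lrt_p < alpha)
    rej = np.asarray(rejections, dtype=float)
    return {
        "rate": float(rej.mean()),
        "se": float(rej.std(ddof=1) / math.sqrt(len(rej))),
        "n_reps": len(rej),
    }


def lrt_variance_recovery(
    n_reps: int = 100, sd_ratio: float = 1 / 3, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Recovery of a planted residual-variance ratio (HPLC over MPMC).

    With ``sd_ratio = 1/3`` the planted variance ratio is 1/9; the study
    reports the geometric-mean fitted ratio and the LRT rejection rate.
    """
    design = generate_design(SimulationConfig())
    seeds = _seed_stream(seed, n_reps)
    log_ratios, rejections = [], []
    sigma_m = 0.3
    for s in seeds:
        rng = np.random.default_rng(s)
        rec = _simulate_shannon(rng, design, sd_ratio * sigma_m, sigma_m)
        fit = fit_diversity_model(rec, design)
        log_ratios.append(math.log(fit.variance_ratio))
        rejections.append(fit.lrt_p < alpha)
    lr = np.asarray(log_ratios)
    return {
        "mean_log_ratio": float(lr.mean()),
        "se_log_ratio": float(lr.std(ddof=1) / math.sqrt(len(lr))),
        "geometric_mean_ratio": float(np.exp(lr.mean())),
        "true_ratio": sd_ratio**2,
        "power": float(np.mean(rejections)),
        "n_reps": len(lr),
    }


def permutation_exactness_study(
    n_instances: int = 12, n_perm: int = 10000, seed: int = 0
) -> dict:
    """Empirical vs exact hypergeometric enrichment p on small universes.

    Random universes of 5-12 ortholog groups, one pathway each; returns the
    largest absolute deviation in binomial-standard-error units.
    """
    rng = np.random.default_rng(seed)
    max_dev_se = 0.0
    for _ in range(n_instances):
        n_obs = int(rng.integers(5, 13))
        universe = [f"og{i}" for i in range(n_obs)]
        k = int(rng.integers(2, n_obs))
        members = set(rng.choice(universe, size=k, replace=False))
        n_draw = int(rng.integers(1, n_obs))
        sig = list(rng.choice(universe, size=n_draw, replace=False))
        mem = PathwayMembership(
            pairs=pd.DataFrame(
                [(og, "P") for og in members], columns=["ortholog_group", "pathway"]
            )
        )
        res = permutation_enrichment(
            mem, universe, sig, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        n_sig = len(members & set(sig))
        p_exact = hypergeometric_tail(n_obs, k, n_draw, n_sig)
        se = max(math.sqrt(p_exact * (1 - p_exact) / n_perm), 1.0 / n_perm)
        max_dev_se = max(max_dev_se, abs(res[0].p_empirical - p_exact) / se)
    return {"max_abs_deviation_se_units": max_dev_se, "n_instances": n_instances,
            "n_perm": n_perm}


def _brute_force_min_cover_size(universe: set, sets: dict) -> int:
    names = sorted(sets)
    for size in range(len(names) + 1):
        for combo in itertools.combinations(names, size):
            cov = set().union(*(sets[c] for c in combo)) if combo else set()
            if universe <= cov:
                return size
    return len(names)


def minpath_exactness_study(n_instances: int = 25, seed: int = 0) -> dict:
    """Parsimony solver vs exhaustive search on random instances (<=12 pathways)."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_instances):
        n_ogs = int(rng.integers(4, 15))
        n_pw = int(rng.integers(2, 13))
        ogs = [f"k{i}" for i in range(n_ogs)]
        sets = {
            f"P{j}": set(
                rng.choice(ogs, size=int(rng.integers(1, n_ogs + 1)), replace=False)
            )
            for j in range(n_pw)
        }
        mem = PathwayMembership(
            pairs=pd.DataFrame(
                [(og, pw) for pw, m in sets.items() for og in m],
                columns=["ortholog_group", "pathway"],
            )
        )
        universe = set().union(*sets.values())
        retained, _, _, solver = minimal_pathway_set(universe, mem)
        covered = set().union(*(sets[p] for p in retained))
        ok = (
            solver == "exact"
            and universe <= covered
            and len(retained) == _brute_force_min_cover_size(universe, sets)
        )
        matches += ok
    return {"match_rate": matches / n_instances, "n_instances": n_instances}


def rarefaction_expectation_study(replicates: int = 2000, seed: int = 0) -> dict:
    """Monte-Carlo rarefied richness vs the analytic hypergeometric expectation."""
    vectors = [
        ([5, 3, 2], 5),
        ([40, 10, 5, 2, 1], 20),
        ([100, 1, 1, 1], 10),
    ]
    max_dev_se = 0.0
    for i, (counts, depth) in enumerate(vectors):
        df = pd.DataFrame({"s": counts}, index=[f"sp{j}" for j in range(len(counts))])
        table = CountTable(counts=df, level="species")
        curves = rarefy(table, depths=[depth], replicates=replicates, seed=seed + i)
        exp = expected_rarefied_richness(counts, depth)
        mc = curves["richness"].to_numpy(dtype=float)
        se = max(mc.std(ddof=1) / math.sqrt(len(mc)), 1e-12)
        max_dev_se = max(max_dev_se, abs(mc.mean() - exp) / se)
    return {"max_abs_deviation_se_units": max_dev_se, "replicates": replicates,
            "n_vectors": len(vectors)}
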