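"""Shannon diversity, variance-heterogeneity testing, and rarefaction.

Shannon indices (natural log) are computed from species counts per sample
and compared between diets with a linear mixed model: kitten random
intercepts, categorical diet, week and their interaction, and diet-specific
residual variances fitted by ML. Variance heterogeneity between diets is
tested by a likelihood-ratio test against the common-variance model on a
chi-square(1) reference.

Rarefaction subsamples reads without replacement (multivariate
hypergeometric draws on the count vector — counts are a sufficient
statistic for shuffling per-read records) at a grid of depths with
replicated draws, and models richness with time-nested-in-kitten random
effects and residual variance weighted by subsample depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .mixed import LMMFit, fit_lmm
from .tables import CountTable

logger = logging.getLogger(__name__)


def shannon_index(counts) -> float:
    """H = -sum p_i ln p_i over positive-count species (nats)."""
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or (x < 0).any():
        raise ValueError("counts must be non-negative and non-empty")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no defined diversity")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_records(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon index H and observed richness R."""
    rows = []
    for s in table.sample_ids:
        col = table.counts[s]
        rows.append(
            {
                "sample_id": s,
                "H": shannon_index(col.to_numpy()),
                "R": int((col > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _diet_week_design(meta: pd.DataFrame, terms: tuple[str, ...]):
    diet = (meta["diet"] != "HPLC").astype(float).to_numpy()
    weeks = np.sort(meta["week"].unique())
    cols, names = [np.ones(len(meta))], ["const"]
    term_cols: dict[str, list[int]] = {}
    if "diet" in terms:
        term_cols["diet"] = [len(cols)]
        cols.append(diet)
        names.append("diet[MPMC]")
    if "week" in terms:
        term_cols["week"] = []
        for w in weeks[1:]:
            term_cols["week"].append(len(cols))
            cols.append((meta["week"] == w).astype(float).to_numpy())
            names.append(f"week[{w}]")
    if "diet:week" in terms:
        term_cols["diet:week"] = []
        for w in weeks[1:]:
            term_cols["diet:week"].append(len(cols))
            cols.append(diet * (meta["week"] == w).astype(float).to_numpy())
            names.append(f"diet:week[{w}]")
    return np.column_stack(cols), names, term_cols


@dataclass
class DiversityModelFit:
    terms: tuple[str, ...]
    beta: dict
    wald_p: dict
    tau2_kitten: float
    sigma2_by_diet: dict
    loglik_het: float
    loglik_hom: float
    lrt_stat: float
    lrt_p: float
    singular: bool

    @property
    def variance_ratio(self) -> float:
        """sigma2_HPLC / sigma2_MPMC."""
        return self.sigma2_by_diet["HPLC"] / self.sigma2_by_diet["MPMC"]


def fit_diversity_model(
    records: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> DiversityModelFit:
    """Heteroscedastic kitten-random-intercept model of Shannon diversity.

    Fixed effects diet, week, diet:week are backward-eliminated at
    ``alpha`` (interaction first, then week; diet is retained for
    reporting). The heterogeneity LRT compares diet-specific vs pooled
    residual variances under the final fixed structure.
    """
    meta = metadata.loc[records.index]
    if meta.groupby("diet")["kitten"].nunique().min() < 2:
        raise ValueError("need >= 2 kittens per diet")
    y = records["H"].to_numpy(dtype=float)
    cluster = meta["kitten"].to_numpy()
    rg = meta["diet"].to_numpy()

    def _fit(terms, het):
        X, names, term_cols = _diet_week_design(meta, terms)
        fit = fit_lmm(
            y, X, cluster, beta_names=names, resid_group=rg if het else None, reml=True
        )
        return fit, term_cols

    terms: tuple[str, ...] = ("diet", "week", "diet:week")
    if meta["week"].nunique() < 2:
        terms = ("diet",)
    fit, term_cols = _fit(terms, het=True)
    pvals = {t: fit.wald_p(ix) for t, ix in term_cols.items()}
    if "diet:week" in terms and pvals["diet:week"] >= alpha:
        terms = ("diet", "week")
        fit, term_cols = _fit(terms, het=True)
        pvals.update({t: fit.wald_p(ix) for t, ix in term_cols.items()})
        if pvals["week"] >= alpha:
            terms = ("diet",)
            fit, term_cols = _fit(terms, het=True)
            pvals["diet"] = fit.wald_p(term_cols["diet"])

    hom_fit, _ = _fit(terms, het=False)
    lrt = max(0.0, 2.0 * (fit.loglik - hom_fit.loglik))
    return DiversityModelFit(
        terms=terms,
        beta=dict(zip(fit.beta_names, fit.beta)),
        wald_p=pvals,
        tau2_kitten=fit.tau2_cluster,
        sigma2_by_diet=dict(fit.sigma2),
        loglik_het=fit.loglik,
        loglik_hom=hom_fit.loglik,
        lrt_stat=lrt,
        lrt_p=float(chi2.sf(lrt, 1)),
        singular=fit.singular or hom_fit.singular,
    )


def rarefy(
    table: CountTable,
    depths,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefied richness per sample x depth x replicate.

    Draws are without replacement (multivariate hypergeometric on the count
    vector); richness is the number of species with at least one read in
    the subsample. Depths exceeding a sample's total are skipped with a
    warning.
    """
    depths = [int(d) for d in depths]
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for s in table.sample_ids:
        vec = table.counts[s].to_numpy()
        total = int(vec.sum())
        for d in depths:
            if d > total:
                logger.warning("sample %s: depth %d exceeds total %d; skipped", s, d, total)
                continue
            for r in range(replicates):
                draw = rng.multivariate_hypergeometric(vec, d)
                rows.append(
                    {
                        "sample_id": s,
                        "depth": d,
                        "replicate": r,
                        "richness": int((draw > 0).sum()),
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["seed"] = seed
    return out


def expected_rarefied_richness(counts, depth: int) -> float:
    """Analytic E[richness] = sum_i (1 - C(N - n_i, d) / C(N, d)).

    Uses log-gamma arithmetic; the exact hypergeometric-expectation oracle
    for the Monte-Carlo subsampler.
    """
    from scipy.special import gammaln

    x = np.asarray(counts, dtype=float)
    N = x.sum()
    if depth > N:
        raise ValueError("depth exceeds total")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    terms = []
    for n_i in x:
        if n_i <= 0:
            continue
        if N - n_i < depth:
            terms.append(1.0)
        else:
            terms.append(1.0 - np.exp(log_comb(N - n_i, depth) - log_comb(N, depth)))
    return float(np.sum(terms))


@dataclass
class RarefactionModelFit:
    terms: tuple[str, ...]
    beta: dict
    wald_p: dict
    diet_p: float
    tau2_kitten: float
    tau2_week_in_kitten: float
    sigma2: float
    singular: bool


def fit_rarefaction_model(
    curves: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> RarefactionModelFit:
    """Mixed model of rarefied richness with depth-weighted residuals.

    richness ~ diet * depth(categorical) with random intercepts for kitten
    and for week within kitten, residual variance proportional to 1/depth
    ("weighting by the number of sequences"). The diet contrast p-value is
    from the final model after backward elimination of the interaction.
    """
    df = curves.join(metadata, on="sample_id")
    if df["diet"].nunique() < 2:
        raise ValueError("diet contrast requires both diets")
    depths = np.sort(df["depth"].unique())
    if len(depths) < 2:
        logger.warning("single depth: depth terms dropped from the model")

    y = df["richness"].to_numpy(dtype=float)
    cluster = df["kitten"].to_numpy()
    sub = (df["kitten"].astype(str) + ":" + df["week"].astype(str)).to_numpy()
    weights = df["depth"].to_numpy(dtype=float) / df["depth"].mean()

    diet = (df["diet"] != "HPLC").astype(float).to_numpy()

    def _design(terms):
        cols, names = [np.ones(len(df))], ["const"]
        term_cols: dict[str, list[int]] = {"diet": [1]}
        cols.append(diet)
        names.append("diet[MPMC]")
        if "depth" in terms and len(depths) > 1:
            term_cols["depth"] = []
            for d in depths[1:]:
                term_cols["depth"].append(len(cols))
                cols.append((df["depth"] == d).astype(float).to_numpy())
                names.append(f"depth[{d}]")
        if "diet:depth" in terms and len(depths) > 1:
            term_cols["diet:depth"] = []
            for d in depths[1:]:
                term_cols["diet:depth"].append(len(cols))
                cols.append(diet * (df["depth"] == d).astype(float).to_numpy())
                names.append(f"diet:depth[{d}]")
        return np.column_stack(cols), names, term_cols

    def _fit(terms):
        X, names, term_cols = _design(terms)
        fit = fit_lmm(
            y, X, cluster, beta_names=names, subcluster=sub, weights=weights, reml=True
        )
        return fit, term_cols

    terms: tuple[str, ...] = ("diet", "depth", "diet:depth")
    fit, term_cols = _fit(terms)
    pvals = {t: fit.wald_p(ix) for t, ix in term_cols.items()}
    if "diet:depth" in term_cols and pvals["diet:depth"] >= alpha:
        terms = ("diet", "depth")
        fit, term_cols = _fit(terms)
        pvals.update({t: fit.wald_p(ix) for t, ix in term_cols.items()})
    return RarefactionModelFit(
        terms=terms,
        beta=dict(zip(fit.beta_names, fit.beta)),
        wald_p=pvals,
        diet_p=pvals["diet"],
        tau2_kitten=fit.tau2_cluster,
        tau2_week_in_kitten=float(fit.tau2_subcluster or 0.0),
        sigma2=float(list(fit.sigma2.values())[0]),
        singular=fit.singular,
    )
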