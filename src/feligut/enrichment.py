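"""Permutation test for pathway over-representation of significant features.

For each pathway, the number of observed member ortholog groups (n_found)
and the number in the significant set (n_sig) are counted; an ortholog
group belonging to several pathways contributes to all of them. Random
subsets of the observed universe, of the same size as the significant set,
are drawn without replacement; the empirical p-value is the fraction of
subsets whose member count in the pathway is >= n_sig. Under the null this
converges to the hypergeometric tail P(X >= n_sig) with population
n_observed, successes n_found and draws |significant|.

The universe is the set of ortholog groups that entered testing (after the
zero filter), and pathways "tested" are those with at least one observed
member; the Sidak critical level for the over-representation flag uses
that count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffabund import sidak_critical
from .tables import PathwayMembership


@dataclass
class EnrichmentResult:
    pathway_id: str
    n_db: int
    n_found: int
    n_sig: int
    n_mpmc: int
    n_hplc: int
    p_empirical: float
    over_represented: bool

    def to_row(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "n_db": self.n_db,
            "n_found": self.n_found,
            "n_sig": self.n_sig,
            "n_mpmc": self.n_mpmc,
            "n_hplc": self.n_hplc,
            "p_empirical": self.p_empirical,
            "over_represented": self.over_represented,
        }


def count_pathway_membership(
    observed_ogs, significant_ogs, membership: PathwayMembership
) -> pd.DataFrame:
    """Per-pathway (n_found, n_sig) over the observed universe."""
    observed = set(observed_ogs)
    significant = set(significant_ogs)
    stray = significant - observed
    if stray:
        raise ValueError(f"significant ortholog groups not in observed set: {sorted(stray)[:5]}")
    rows = []
    for pw, members in sorted(membership.as_dict().items()):
        found = members & observed
        rows.append(
            {
                "pathway_id": pw,
                "n_found": len(found),
                "n_sig": len(found & significant),
            }
        )
    return pd.DataFrame(rows).set_index("pathway_id")


def split_directions(significant_ogs, feature_results: pd.DataFrame) -> tuple[int, int]:
    """Tally significant members by direction: OR > 1 -> MPMC, OR < 1 -> HPLC."""
    n_mpmc = n_hplc = 0
    for og in significant_ogs:
        or_ = float(feature_results.loc[og, "odds_ratio"])
        if not np.isfinite(or_):
            raise ValueError(f"{og}: significant member without an odds ratio")
        if or_ > 1:
            n_mpmc += 1
        elif or_ < 1:
            n_hplc += 1
        else:
            raise ValueError(f"{og}: odds ratio exactly 1 contradicts significance")
    return n_mpmc, n_hplc


def permutation_enrichment(
    membership: PathwayMembership,
    observed_ogs,
    significant_ogs,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    feature_results: pd.DataFrame | None = None,
    add_one: bool = False,
) -> list[EnrichmentResult]:
    """Empirical over-representation p-values by subset resampling.

    ``add_one`` switches the estimate from r/n_perm (the plain percentage
    of subsets, which can return exactly 0) to the positively biased but
    never-zero (r+1)/(n_perm+1).
    """
    observed = sorted(set(observed_ogs))
    significant = sorted(set(significant_ogs))
    if len(significant) > len(observed):
        raise ValueError("significant set larger than observed universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = count_pathway_membership(observed, significant, membership)
    tested = counts.index[counts["n_found"] >= 1]
    critical = sidak_critical(alpha, len(tested)) if len(tested) else np.nan

    og_index = {og: i for i, og in enumerate(observed)}
    pathways = list(tested)
    member_matrix = np.zeros((len(pathways), len(observed)), dtype=bool)
    as_dict = membership.as_dict()
    for r, pw in enumerate(pathways):
        for og in as_dict[pw]:
            if og in og_index:
                member_matrix[r, og_index[og]] = True

    rng = np.random.default_rng(seed)
    s = len(significant)
    n_obs = len(observed)
    exceed = np.zeros(len(pathways), dtype=np.int64)
    n_sig_vec = counts.loc[pathways, "n_sig"].to_numpy()
    for _ in range(n_perm):
        idx = rng.choice(n_obs, size=s, replace=False)
        rand_counts = member_matrix[:, idx].sum(axis=1)
        exceed += rand_counts >= n_sig_vec

    if add_one:
        p_emp = (exceed + 1) / (n_perm + 1)
    else:
        p_emp = exceed / n_perm

    results = []
    for r, pw in enumerate(pathways):
        n_sig = int(n_sig_vec[r])
        if feature_results is not None and n_sig > 0:
            members_sig = sorted(as_dict[pw] & set(significant))
            n_mpmc, n_hplc = split_directions(members_sig, feature_results)
        else:
            n_mpmc = n_hplc = 0
        results.append(
            EnrichmentResult(
                pathway_id=pw,
                n_db=membership.database_size.get(pw, int(counts.loc[pw, "n_found"])),
                n_found=int(counts.loc[pw, "n_found"]),
                n_sig=n_sig,
                n_mpmc=n_mpmc,
                n_hplc=n_hplc,
                p_empirical=float(p_emp[r]),
                over_represented=bool(p_emp[r] < critical),
            )
        )
    results.sort(key=lambda e: (e.p_empirical, e.pathway_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results]).set_index("pathway_id")


def hypergeometric_tail(n_observed: int, n_found: int, n_draws: int, n_sig: int) -> float:
    """Exact P(X >= n_sig) for X ~ Hypergeometric(N, K, n) — the oracle the
    permutation estimate converges to."""
    from scipy.stats import hypergeom

    if n_sig <= 0:
        return 1.0
    return float(hypergeom.sf(n_sig - 1, n_observed, n_found, n_draws))
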