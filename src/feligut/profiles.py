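"""Pathway-level abundance profiles, clustering and parsimony filtering.

Pathway abundance in a sample is the sum of the relative abundances of its
member ortholog groups (a group in several pathways contributes fully to
each). Diet means, fold changes with the smaller mean as denominator, and
completeness (observed members / reference pathway size) summarise each
pathway. Profiles are clustered by unweighted average-linkage agglomeration
on Euclidean distances, and a MinPath-style parsimony step finds a
minimum-cardinality pathway set covering all coverable ortholog groups —
pathways outside the set are potential annotation artifacts driven by
promiscuous enzymes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tables import PathwayMembership, RelativeAbundanceTable

logger = logging.getLogger(__name__)

EXACT_SOLVER_LIMIT = 25  # branch-and-bound above this many candidate pathways


def pathway_abundance(
    og_rel_abundance: RelativeAbundanceTable, membership: PathwayMembership
) -> pd.DataFrame:
    """Per-pathway, per-sample abundance: sum of member relative abundances."""
    vals = og_rel_abundance.values
    rows = {}
    for pw, members in membership.as_dict().items():
        present = [m for m in members if m in vals.index]
        rows[pw] = vals.loc[present].sum(axis=0) if present else pd.Series(0.0, index=vals.columns)
    out = pd.DataFrame(rows).T
    out.index.name = "pathway_id"
    return out.sort_index()


def fold_change(mean_hplc: float, mean_mpmc: float) -> tuple[float, str]:
    """max/min fold change and the diet with the larger mean.

    Returns (nan, 'undefined') when both means are zero; an infinite fold
    change (zero min, positive max) is returned as inf — display capping is
    a plotting concern, numeric outputs are uncapped.
    """
    if mean_hplc < 0 or mean_mpmc < 0:
        raise ValueError("means must be non-negative")
    if mean_hplc == mean_mpmc == 0:
        return (float("nan"), "undefined")
    if mean_hplc == mean_mpmc:
        return (1.0, "none")
    lo, hi = sorted([mean_hplc, mean_mpmc])
    fc = float("inf") if lo == 0 else hi / lo
    return (fc, "HPLC" if mean_hplc > mean_mpmc else "MPMC")


def pathway_completeness(n_found: float, n_db: float) -> float:
    """Percentage of a reference pathway's enzyme functions observed."""
    if n_db <= 0:
        raise ValueError("database size must be positive")
    if not 0 <= n_found <= n_db:
        raise ValueError("n_found must lie in [0, n_db]")
    return 100.0 * n_found / n_db


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: pd.Series  # flat labels at the requested k
    item_ids: list[str]
    metric: str = "euclidean"

    def newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.item_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(
    profiles: pd.DataFrame, k: int, metric: str = "euclidean", linkage: str = "average"
) -> ClusterResult:
    """Average-linkage agglomeration on pairwise Euclidean distances.

    ``profiles``: items on rows (pathways or samples), variables on columns.
    Rows are sorted by id first so labels do not depend on input order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    if not 1 <= k <= len(profiles):
        raise ValueError("k must lie in [1, n_items]")
    prof = profiles.sort_index()
    dist = pdist(prof.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        linkage=Z,
        labels=pd.Series(flat, index=prof.index, name="cluster"),
        item_ids=list(prof.index),
        metric=metric,
    )


def mean_pairwise_distance(profiles: pd.DataFrame, metric: str = "euclidean") -> float:
    """Arithmetic mean of all pairwise distances within a group of profiles."""
    if len(profiles) < 2:
        raise ValueError("mean pairwise distance needs >= 2 members")
    return float(pdist(profiles.to_numpy(dtype=float), metric=metric).mean())


# ---------------------------------------------------------------------------
# MinPath-style parsimony


def _greedy_cover(universe: set[str], sets: dict[str, set[str]]) -> list[str]:
    remaining = set(universe)
    chosen: list[str] = []
    while remaining:
        # largest marginal coverage, lexicographic tie-break
        best = min(sets, key=lambda p: (-len(sets[p] & remaining), p))
        gain = sets[best] & remaining
        if not gain:
            break
        chosen.append(best)
        remaining -= gain
    return chosen


def _prune_redundant(chosen: list[str], universe: set[str], sets: dict[str, set[str]]) -> list[str]:
    """Drop any pathway whose removal leaves the cover intact (irredundancy)."""
    kept = list(chosen)
    changed = True
    while changed:
        changed = False
        for p in sorted(kept):
            others = set().union(*(sets[q] for q in kept if q != p)) if len(kept) > 1 else set()
            if universe <= others:
                kept.remove(p)
                changed = True
                break
    return kept


def _exact_cover(universe: set[str], sets: dict[str, set[str]]) -> list[str]:
    """Minimum-cardinality cover by branch and bound over candidate pathways."""
    names = sorted(sets, key=lambda p: (-len(sets[p]), p))
    greedy = _prune_redundant(_greedy_cover(universe, sets), universe, sets)
    best = list(greedy)

    def bound_reachable(remaining, avail_idx):
        if not remaining:
            return 0
        biggest = max((len(sets[names[i]] & remaining) for i in avail_idx), default=0)
        if biggest == 0:
            return None
        return int(np.ceil(len(remaining) / biggest))

    def recurse(idx, chosen, remaining):
        nonlocal best
        if not remaining:
            if len(chosen) < len(best):
                best = list(chosen)
            return
        if idx >= len(names) or len(chosen) + 1 >= len(best):
            return
        avail = range(idx, len(names))
        lb = bound_reachable(remaining, avail)
        if lb is None or len(chosen) + lb >= len(best):
            return
        name = names[idx]
        gain = sets[name] & remaining
        if gain:
            chosen.append(name)
            recurse(idx + 1, chosen, remaining - gain)
            chosen.pop()
        recurse(idx + 1, chosen, remaining)

    recurse(0, [], set(universe))
    return sorted(best)


def minimal_pathway_set(
    observed_ogs, membership: PathwayMembership
) -> tuple[list[str], list[str], list[str], str]:
    """Minimum set of pathways explaining the observed ortholog groups.

    Returns (retained, removed, orphan_ogs, solver). Orphans are observed
    groups in no pathway; they cannot constrain the cover and are reported
    separately. The solver is exact (branch and bound) up to
    ``EXACT_SOLVER_LIMIT`` candidate pathways and greedy set-cover with
    redundancy pruning above that.
    """
    observed = set(observed_ogs)
    sets = {
        pw: members & observed
        for pw, members in membership.as_dict().items()
    }
    candidates = {pw: s for pw, s in sets.items() if s}
    coverable = set().union(*candidates.values()) if candidates else set()
    orphans = sorted(observed - coverable)

    if not candidates:
        return [], sorted(sets), orphans, "exact"

    if len(candidates) <= EXACT_SOLVER_LIMIT:
        solver = "exact"
        retained = _exact_cover(coverable, candidates)
    else:
        solver = "greedy"
        retained = sorted(
            _prune_redundant(_greedy_cover(coverable, candidates), coverable, candidates)
        )
    logger.info("minimal pathway set: %d/%d retained (%s solver)", len(retained), len(sets), solver)
    removed = sorted(set(sets) - set(retained))
    return retained, removed, orphans, solver


def pathway_profiles(
    og_rel_abundance: RelativeAbundanceTable,
    membership: PathwayMembership,
    metadata: pd.DataFrame,
    k_clusters: int = 5,
) -> tuple[pd.DataFrame, ClusterResult]:
    """Full pathway profile table plus the pathway dendrogram.

    Per pathway: mean relative abundance per diet, fold change and
    direction, completeness, cluster label at ``k_clusters`` (on the
    two-diet mean-abundance profile, raw values as plotted), and whether
    the parsimony step retains it.
    """
    abundance = pathway_abundance(og_rel_abundance, membership)
    meta = metadata.loc[abundance.columns]
    means = {
        diet: abundance.loc[:, meta.index[meta["diet"] == diet]].mean(axis=1)
        for diet in ("HPLC", "MPMC")
    }
    profile_matrix = pd.DataFrame(means)
    cluster = hierarchical_cluster(profile_matrix, k=min(k_clusters, len(profile_matrix)))

    observed = set(og_rel_abundance.values.index[(og_rel_abundance.values > 0).any(axis=1)])
    retained, removed, orphans, solver = minimal_pathway_set(observed, membership)
    retained_set = set(retained)

    as_dict = membership.as_dict()
    rows = []
    for pw in abundance.index:
        mh, mm = float(means["HPLC"][pw]), float(means["MPMC"][pw])
        fc, direction = fold_change(mh, mm)
        n_found = len(as_dict[pw] & observed)
        n_db = membership.database_size.get(pw, max(n_found, 1))
        rows.append(
            {
                "pathway_id": pw,
                "mean_rel_abundance_hplc": mh,
                "mean_rel_abundance_mpmc": mm,
                "fold_change": fc,
                "direction": direction,
                "completeness_pct": pathway_completeness(n_found, n_db),
                "cluster": int(cluster.labels[pw]),
                "minpath_retained": pw in retained_set,
                "solver": solver,
            }
        )
    return pd.DataFrame(rows).set_index("pathway_id"), cluster
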