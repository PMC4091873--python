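import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from feligut.profiles import (
    fold_change,
    hierarchical_cluster,
    mean_pairwise_distance,
    minimal_pathway_set,
    pathway_abundance,
    pathway_completeness,
    pathway_profiles,
)
from feligut.tables import PathwayMembership, RelativeAbundanceTable


def _membership(d, sizes=None):
    pairs = pd.DataFrame(
        [(og, pw) for pw, members in d.items() for og in members],
        columns=["ortholog_group", "pathway"],
    )
    return PathwayMembership(pairs=pairs, database_size=dict(sizes or {}))


def _rel(df):
    return RelativeAbundanceTable(values=df, level="ortholog_group")


class TestPathwayAbundance:
    def test_sum_of_members(self):
        rel = _rel(pd.DataFrame({"s1": [0.1, 0.2, 0.05]}, index=["a", "b", "c"]))
        mem = _membership({"P1": {"a", "b"}})
        ab = pathway_abundance(rel, mem)
        assert ab.loc["P1", "s1"] == pytest.approx(0.3)

    def test_shared_og_contributes_to_both(self):
        rel = _rel(pd.DataFrame({"s1": [0.1, 0.2]}, index=["a", "b"]))
        mem = _membership({"P1": {"a", "b"}, "P2": {"b"}})
        ab = pathway_abundance(rel, mem)
        assert ab.loc["P1", "s1"] == pytest.approx(0.3)
        assert ab.loc["P2", "s1"] == pytest.approx(0.2)

    def test_disjoint_union_additivity(self):
        rel = _rel(pd.DataFrame({"s1": [0.1, 0.2, 0.15]}, index=["a", "b", "c"]))
        ab = pathway_abundance(
            rel, _membership({"P1": {"a"}, "P2": {"b", "c"}, "P12": {"a", "b", "c"}})
        )
        assert ab.loc["P12", "s1"] == pytest.approx(ab.loc["P1", "s1"] + ab.loc["P2", "s1"])

    def test_membership_for_unobserved_og_ignored(self):
        rel = _rel(pd.DataFrame({"s1": [0.1]}, index=["a"]))
        ab = pathway_abundance(rel, _membership({"P1": {"a", "zzz"}}))
        assert ab.loc["P1", "s1"] == pytest.approx(0.1)


class TestFoldChange:
    @pytest.mark.parametrize(
        "h,m,fc,direction",
        [
            (0.02, 0.01, 2.0, "HPLC"),
            (0.01, 0.01, 1.0, "none"),
            (0.003, 0.006, 2.0, "MPMC"),
        ],
    )
    def test_known_values(self, h, m, fc, direction):
        assert fold_change(h, m) == (pytest.approx(fc), direction)

    def test_zero_minimum_is_infinite(self):
        fc, direction = fold_change(0.0, 0.01)
        assert np.isinf(fc) and direction == "MPMC"

    def test_both_zero_flagged(self):
        fc, direction = fold_change(0.0, 0.0)
        assert np.isnan(fc) and direction == "undefined"


class TestCompleteness:
    @pytest.mark.parametrize(
        "found,db,pct",
        [
            (84.0, 134.5, 62.5),
            (45.5, 90.8, 50.1),
            (172.2, 244.7, 70.4),
            (0, 10, 0.0),
        ],
    )
    def test_reported_cluster_values(self, found, db, pct):
        assert round(pathway_completeness(found, db), 1) == pct

    def test_zero_database_rejected(self):
        with pytest.raises(ValueError):
            pathway_completeness(1, 0)


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        prof = pd.DataFrame({"x": [1.0, 1.0, 3.0]}, index=["a", "b", "c"])
        res = hierarchical_cluster(prof, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_average_linkage_heights_by_hand(self):
        """1-D {0,2,5}: merge at 2, then at mean(5,3) = 4."""
        prof = pd.DataFrame({"x": [0.0, 2.0, 5.0]}, index=["a", "b", "c"])
        res = hierarchical_cluster(prof, k=2)
        assert res.linkage[:, 2].tolist() == pytest.approx([2.0, 4.0])
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_labels_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"p{i}" for i in range(8)])
        r1 = hierarchical_cluster(prof, k=3)
        r2 = hierarchical_cluster(prof.sample(frac=1, random_state=1), k=3)
        pd.testing.assert_series_equal(r1.labels, r2.labels)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        prof = pd.DataFrame(rng.normal(size=(12, 4)))
        prof.index = [f"p{i}" for i in range(12)]
        res = hierarchical_cluster(prof, k=4)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_k_larger_than_items_rejected(self):
        prof = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            hierarchical_cluster(prof, k=3)

    def test_newick_parses(self):
        prof = pd.DataFrame({"x": [0.0, 2.0, 5.0, 6.0]}, index=list("abcd"))
        nwk = hierarchical_cluster(prof, k=2).newick()
        assert nwk.endswith(";") and nwk.count("(") == 3
        assert all(leaf in nwk for leaf in "abcd")


class TestMeanPairwiseDistance:
    def test_identical_members_zero(self):
        prof = pd.DataFrame({"x": [1.0, 1.0]})
        assert mean_pairwise_distance(prof) == 0.0

    def test_hand_value(self):
        prof = pd.DataFrame({"x": [0.0, 2.0, 4.0]})
        assert mean_pairwise_distance(prof) == pytest.approx(8 / 3)

    def test_homogeneity(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.normal(size=(5, 3)))
        assert mean_pairwise_distance(prof * 3.0) == pytest.approx(
            3.0 * mean_pairwise_distance(prof)
        )

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_distance(pd.DataFrame({"x": [1.0]}))


def _brute_force_min_cover(universe, sets):
    names = sorted(sets)
    for size in range(len(names) + 1):
        for combo in itertools.combinations(names, size):
            if universe <= set().union(*(sets[c] for c in combo)) if combo else not universe:
                return size
    return len(names)


class TestMinimalPathwaySet:
    def test_redundant_subset_pathway_removed(self):
        mem = _membership({"P1": {"k1", "k2"}, "P2": {"k1"}})
        retained, removed, orphans, solver = minimal_pathway_set({"k1", "k2"}, mem)
        assert retained == ["P1"] and removed == ["P2"] and orphans == []

    def test_disjoint_unique_members_all_retained(self):
        mem = _membership({"P1": {"a"}, "P2": {"b"}, "P3": {"c"}})
        retained, removed, _, _ = minimal_pathway_set({"a", "b", "c"}, mem)
        assert retained == ["P1", "P2", "P3"] and removed == []

    def test_orphans_reported(self):
        mem = _membership({"P1": {"a"}})
        retained, _, orphans, _ = minimal_pathway_set({"a", "zzz"}, mem)
        assert retained == ["P1"] and orphans == ["zzz"]

    def test_exact_matches_exhaustive_minimum_on_random_instances(self):
        rng = np.random.default_rng(77)
        for trial in range(25):
            n_ogs = int(rng.integers(4, 15))
            n_pw = int(rng.integers(2, 12))
            ogs = [f"k{i}" for i in range(n_ogs)]
            sets = {
                f"P{j}": set(rng.choice(ogs, size=int(rng.integers(1, n_ogs + 1)),
                                        replace=False))
                for j in range(n_pw)
            }
            mem = _membership(sets)
            universe = set().union(*sets.values())
            retained, removed, orphans, solver = minimal_pathway_set(universe, mem)
            assert solver == "exact"
            covered = set().union(*(sets[p] for p in retained))
            assert universe <= covered
            assert len(retained) == _brute_force_min_cover(universe, sets)

    def test_greedy_cover_valid_and_irredundant_above_exact_limit(self):
        rng = np.random.default_rng(8)
        n_pw, n_ogs = 40, 60
        ogs = [f"k{i}" for i in range(n_ogs)]
        sets = {
            f"P{j:02d}": set(rng.choice(ogs, size=int(rng.integers(1, 12)), replace=False))
            for j in range(n_pw)
        }
        mem = _membership(sets)
        universe = set().union(*sets.values())
        retained, removed, orphans, solver = minimal_pathway_set(universe, mem)
        assert solver == "greedy"
        covered = set().union(*(sets[p] for p in retained))
        assert universe <= covered
        for p in retained:  # irredundancy: dropping any retained pathway breaks cover
            rest = set().union(*(sets[q] for q in retained if q != p)) if len(retained) > 1 else set()
            assert not universe <= rest


class TestPathwayProfiles:
    def test_profiles_table_well_formed(self, small_study):
        cfg, design, table, truth = small_study
        from feligut.simulate import generate_pathway_membership
        from feligut.tables import to_relative_abundance

        mem, _ = generate_pathway_membership(cfg, table.feature_ids, truth)
        rel = to_relative_abundance(table, denominator="annotated_total")
        prof, cluster = pathway_profiles(rel, mem, design, k_clusters=4)
        assert prof["completeness_pct"].between(0, 100).all()
        fc = prof["fold_change"].dropna()
        assert (fc[np.isfinite(fc)] >= 1).all()
        assert prof["cluster"].nunique() <= 4
        assert prof["minpath_retained"].any()

    def test_strong_diet_effect_separates_sample_dendrogram(self):
        """Samples cluster by diet when many features carry large effects."""
        from feligut.simulate import SimulationConfig, generate_counts, generate_design
        from feligut.tables import to_relative_abundance

        cfg = SimulationConfig(
            n_features=60,
            prop_features_affected=0.5,
            diet_effect_log_or=2.5,
            kitten_effect_sd=0.1,
            base_abundance_logsigma=1.0,
            seed=6,
        )
        design = generate_design(cfg)
        table, _ = generate_counts(cfg, design)
        rel = to_relative_abundance(table)
        res = hierarchical_cluster(rel.values.T, k=2)
        labels = res.labels
        diets = design.loc[labels.index, "diet"]
        # one cluster should be (almost) pure HPLC, the other (almost) pure MPMC
        purity = (
            pd.crosstab(labels, diets).max(axis=1).sum() / len(labels)
        )
        assert purity > 0.9
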