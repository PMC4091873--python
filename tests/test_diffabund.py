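import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from feligut.diffabund import (
    filter_zero_heavy,
    fit_feature_gee,
    run_differential_abundance,
    sidak_critical,
)
from feligut.simulate import SimulationConfig, generate_counts, generate_design
from feligut.tables import CountTable

from conftest import balanced_metadata


class TestSidak:
    @pytest.mark.parametrize(
        "m,expected",
        [(578, 0.000089), (230, 0.000223)],
    )
    def test_printed_critical_values(self, m, expected):
        assert round(sidak_critical(0.05, m), 6) == expected

    def test_single_test_is_alpha(self):
        assert sidak_critical(0.05, 1) == pytest.approx(0.05)

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            sidak_critical(0.05, 0)

    @given(m=st.integers(1, 10**6), alpha=st.floats(0.001, 0.2))
    @settings(derandomize=True, max_examples=50)
    def test_bounds_and_monotonicity(self, m, alpha):
        c = sidak_critical(alpha, m)
        assert 0 < c <= alpha * (1 + 1e-12)
        if m > 1:
            assert c < sidak_critical(alpha, m - 1)

    def test_bonferroni_agreement_for_large_m(self):
        # exact limit of the ratio is -ln(1-a)/a = 1.0259 at a = 0.05
        for m in (10**3, 10**5, 10**7):
            assert sidak_critical(0.05, m) == pytest.approx(0.05 / m, rel=0.03)


class TestZeroFilter:
    def _table(self, zero_counts: int, n=36):
        row = np.ones(n, dtype=int) * 5
        row[:zero_counts] = 0
        df = pd.DataFrame(
            {f"s{i}": [row[i], 3] for i in range(n)}, index=["target", "keeper"]
        )
        return CountTable(counts=df, level="genus")

    def test_boundary_retained_at_exactly_25_percent(self):
        kept, excluded = filter_zero_heavy(self._table(9))
        assert "target" in kept.feature_ids and excluded == []

    def test_excluded_above_25_percent(self):
        kept, excluded = filter_zero_heavy(self._table(10))
        assert excluded == ["target"]

    def test_all_positive_retained(self):
        kept, excluded = filter_zero_heavy(self._table(0))
        assert excluded == []


def _irls_logistic(y, n, X, maxiter=100, tol=1e-12):
    """Independent IRLS oracle for binomial-logit MLE (counts y of n)."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = n * mu * (1 - mu)
        z = eta + (y - n * mu) / W
        new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


class TestFeatureGEE:
    def test_matches_logistic_mle_with_independent_clusters(self):
        """One observation per cluster: GEE estimate equals the ordinary MLE."""
        rng = np.random.default_rng(4)
        meta = balanced_metadata(n_per_diet=10, weeks=(8,))
        n = rng.integers(500, 2000, len(meta)).astype(float)
        diet = (meta["diet"] == "MPMC").astype(float).to_numpy()
        p = 1 / (1 + np.exp(-(-2.0 + 0.8 * diet)))
        y = rng.binomial(n.astype(int), p).astype(float)
        counts = pd.Series(y, index=meta.index, name="f1")
        totals = pd.Series(n, index=meta.index)

        res = fit_feature_gee(counts, totals, meta, working_correlation="independence")
        X = np.column_stack([np.ones(len(meta)), diet])
        beta_mle = _irls_logistic(y, n, X)
        assert res.beta_diet == pytest.approx(beta_mle[1], abs=1e-6)

    def test_label_swap_inverts_odds_ratio(self, small_study):
        _, design, table, _ = small_study
        totals = table.annotated_total
        f = table.counts.sum(axis=1).idxmax()
        res = fit_feature_gee(table.counts.loc[f], totals, design, critical_p=0.01)
        swapped = design.copy()
        swapped["diet"] = swapped["diet"].map({"HPLC": "MPMC", "MPMC": "HPLC"})
        res_sw = fit_feature_gee(table.counts.loc[f], totals, swapped, critical_p=0.01)
        assert res.odds_ratio * res_sw.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_separation_flagged_without_estimates(self, study_design):
        zeros = pd.Series(0, index=study_design.index, name="sep")
        zeros[study_design["diet"] == "MPMC"] = 50
        totals = pd.Series(1000, index=study_design.index)
        res = fit_feature_gee(zeros, totals, study_design)
        assert res.separation and not res.converged
        assert np.isnan(res.beta_diet)

    def test_backward_elimination_keeps_interaction_when_planted(self):
        """A strong planted diet-by-week flip retains the interaction term."""
        rng = np.random.default_rng(11)
        meta = balanced_metadata()
        diet = (meta["diet"] == "MPMC").astype(float).to_numpy()
        late = (meta["week"] > 8).astype(float).to_numpy()
        eta = -3 + 2.5 * diet * late
        p = 1 / (1 + np.exp(-eta))
        n = np.full(len(meta), 50000)
        y = rng.binomial(n, p).astype(float)
        res = fit_feature_gee(
            pd.Series(y, index=meta.index, name="fx"),
            pd.Series(n.astype(float), index=meta.index),
            meta,
            critical_p=0.01,
        )
        assert "diet:week" in res.model_terms
        assert res.interaction_significant


class TestRunDifferentialAbundance:
    def test_classification_invariant_to_row_and_column_order(self, small_study):
        _, design, table, _ = small_study
        res = run_differential_abundance(table, design, alpha=0.05)
        rng = np.random.default_rng(0)
        rows = rng.permutation(table.feature_ids)
        cols = rng.permutation(table.sample_ids)
        shuffled = CountTable(
            counts=table.counts.loc[rows, cols],
            level=table.level,
            annotated_total=table.annotated_total[cols],
        )
        res2 = run_differential_abundance(shuffled, design, alpha=0.05)
        f1 = res.to_frame().sort_index()
        f2 = res2.to_frame().sort_index()
        pd.testing.assert_series_equal(f1["diet_significant"], f2["diet_significant"])
        assert res.threshold.critical_p == res2.threshold.critical_p

    def test_m_counts_prefilter_features(self, small_study):
        _, design, table, _ = small_study
        res = run_differential_abundance(table, design)
        assert res.threshold.m == table.shape[0]
        assert res.threshold.critical_p == sidak_critical(0.05, table.shape[0])

    def test_empty_table_rejected(self, study_design):
        df = pd.DataFrame({"s": [1]}, index=["a"]).iloc[:0]
        with pytest.raises(Exception):
            run_differential_abundance(
                CountTable(counts=df, level="genus"), study_design
            )

    def test_planted_large_effect_detected_and_specific(self):
        """One rare-ish feature with a strong planted effect is the one flagged.

        The planted feature must hold a small share of reads: a large shift
        on a dominant feature moves every other proportion through the
        compositional constraint, which is genuine marginal signal.
        """
        detected, false_flags = 0, 0
        n_reps = 6
        for rep in range(n_reps):
            cfg = SimulationConfig(
                n_features=40,
                base_abundance_logsigma=0.6,
                prop_features_affected=1 / 40,
                diet_effect_log_or=2.5,
                library_size_mean=5e4,
                seed=100 + rep,
            )
            design = generate_design(cfg)
            table, truth = generate_counts(cfg, design)
            res = run_differential_abundance(table, design)
            sig = set(res.significant_features)
            if set(truth.affected_features) <= sig:
                detected += 1
            false_flags += len(sig - set(truth.affected_features))
        assert detected >= n_reps - 1
        assert false_flags <= 1
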