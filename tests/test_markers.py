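import numpy as np
import pandas as pd
import pytest

import trajlens as tl
from trajlens.features import FeatureMatrix
from trajlens.lexicon import CategoryLexicon
from trajlens.markers import (
    dichotomize,
    filter_significant,
    fit_marker_model,
    lasso_screen,
    prune_hierarchy,
    run_marker_cascade,
)
from trajlens.simulate import MARKER_ODDS_RATIOS, simulate_marker_table


def comparisons_frame(rows):
    return pd.DataFrame(rows, columns=["category", "period", "p"]).assign(
        rr=1.0, se=0.1, stars="", n_high=10, n_low=10, status="ok"
    )


class TestFilterSignificant:
    def test_keeps_any_significant_period(self):
        df = comparisons_frame(
            [
                ("anger", "T5", 0.20), ("anger", "T6", 0.01), ("anger", "T7", 0.9),
                ("sad", "T5", 0.50), ("sad", "T6", 0.60), ("sad", "T7", 0.7),
            ]
        )
        got = filter_significant(df, periods=("T5", "T6", "T7"))
        assert got.categories == ("anger",)
        reasons = dict((c, r) for c, _, r in got.audit)
        assert reasons["sad"].startswith("no period")

    def test_threshold_is_inclusive(self):
        df = comparisons_frame([("anger", "T5", 0.05)])
        got = filter_significant(df, periods=("T5",))
        assert got.categories == ("anger",)

    def test_all_null_warns_empty(self):
        df = comparisons_frame([("anger", "T5", 0.5), ("sad", "T5", 0.5)])
        with pytest.warns(UserWarning, match="no category"):
            got = filter_significant(df, periods=("T5",))
        assert got.categories == ()

    def test_missing_period_rejected(self):
        df = comparisons_frame([("anger", "T5", 0.01)])
        with pytest.raises(ValueError, match="T6"):
            filter_significant(df, periods=("T5", "T6"))


class TestPruneHierarchy:
    lex = CategoryLexicon(
        categories=("negemo", "anger", "sad", "motion"),
        patterns={
            "negemo": frozenset({"bad"}),
            "anger": frozenset({"mad"}),
            "sad": frozenset({"cry"}),
            "motion": frozenset({"go"}),
        },
        hierarchy={"negemo": ("anger", "sad")},
    )

    def _set(self, cats):
        from trajlens.markers import MarkerCandidateSet

        return MarkerCandidateSet(stage="significant", categories=tuple(cats))

    def test_parent_removed_when_child_present(self):
        got = prune_hierarchy(self._set(["negemo", "anger"]), self.lex)
        assert got.categories == ("anger",)

    def test_unrelated_candidates_unchanged(self):
        got = prune_hierarchy(self._set(["anger", "motion"]), self.lex)
        assert got.categories == ("anger", "motion")

    def test_transitive_ancestors_pruned(self, toy_lex):
        # affect > negemo > anger: both ancestors drop when anger stays
        got = prune_hierarchy(self._set(["affect", "negemo", "anger"]), toy_lex)
        assert got.categories == ("anger",)


class TestDichotomize:
    def _matrix(self, hits, words):
        n = len(hits)
        return FeatureMatrix(
            user_ids=[f"u{i}" for i in range(n)],
            period_labels=("T5", "T6", "T7"),
            categories=("cat",),
            hits=np.asarray(hits, dtype=int)[:, :, None],
            total_words=np.asarray(words, dtype=int),
        )

    def test_truth_table(self):
        m = self._matrix(
            hits=[[0, 0, 0], [0, 2, 0], [0, 0, 0]],
            words=[[100, 100, 100], [100, 1000, 100], [0, 0, 0]],
        )
        table = dichotomize(m, ["cat"], periods=("T5", "T6", "T7"))
        # (0,0,0) -> 0; (0,0.002,0) -> 1; all-missing -> 0
        assert table["cat"].tolist() == [0, 1, 0]

    def test_missing_periods_count_as_zero_usage(self):
        m = self._matrix(hits=[[3, 0, 0]], words=[[100, 0, 0]])
        table = dichotomize(m, ["cat"])
        assert table["cat"].tolist() == [1]


class TestLassoScreen:
    def test_duplicated_column_at_most_one_survives(self):
        rng = np.random.default_rng(0)
        n = 600
        x = (rng.random(n) < 0.5).astype(int)
        noise = (rng.random(n) < 0.4).astype(int)
        y = (rng.random(n) < 0.2 + 0.5 * x).astype(int)
        table = pd.DataFrame({"a": x, "a_copy": x, "b": noise})
        got = lasso_screen(table, y, n_folds=5, seed=1)
        assert sum(c in got.categories for c in ("a", "a_copy")) <= 1

    def test_null_effects_heavily_shrunk(self):
        # with no real signal, CV-chosen penalties keep few survivors
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n = 400
            X = pd.DataFrame(
                {f"m{k}": (rng.random(n) < 0.5).astype(int) for k in range(8)}
            )
            y = (rng.random(n) < 0.3).astype(int)
            got = lasso_screen(X, y, n_folds=5, seed=s)
            hits += len(got.categories) <= 2
        assert hits >= 8

    def test_degenerate_outcome_rejected(self):
        X = pd.DataFrame({"a": [0, 1] * 50, "b": [1, 0] * 50})
        with pytest.raises(ValueError, match="one class"):
            lasso_screen(X, np.zeros(100), n_folds=5, seed=0)

    def test_needs_two_candidates(self):
        X = pd.DataFrame({"a": [0, 1] * 50})
        with pytest.raises(ValueError, match="at least 2"):
            lasso_screen(X, np.array([0, 1] * 50), n_folds=5, seed=0)


class TestFitMarkerModel:
    def test_two_by_two_equals_cross_product_ratio(self):
        # 40/60 exposed vs 10/90 unexposed -> OR = (40*90)/(60*10) = 6
        x = np.array([1] * 100 + [0] * 100)
        y = np.array([1] * 40 + [0] * 60 + [1] * 10 + [0] * 90)
        model = fit_marker_model(pd.DataFrame({"m": x}), y)
        assert model.table.loc["m", "odds_ratio"] == pytest.approx(6.0, abs=1e-6)

    def test_null_marker_or_near_one(self):
        rng = np.random.default_rng(5)
        x = (rng.random(2000) < 0.5).astype(int)
        y = (rng.random(2000) < 0.3).astype(int)
        model = fit_marker_model(pd.DataFrame({"m": x}), y)
        row = model.table.loc["m"]
        assert row["odds_ratio"] == pytest.approx(1.0, abs=0.3)
        assert row["p"] > 0.05 and row["direction"] == "n.s."

    def test_perfect_separation_raises_informative(self):
        x = np.array([1] * 50 + [0] * 50)
        model_err = None
        with pytest.raises(RuntimeError, match="separation"):
            fit_marker_model(pd.DataFrame({"m": x}), x.copy())

    def test_or_recovery_within_three_se(self):
        """Across seeded replicates, each published generating log-OR is
        recovered within 3 SE by the multivariate refit."""
        ok = total = 0
        for rep in range(12):
            table, groups = simulate_marker_table(6163, seed=1000 + rep)
            model = fit_marker_model(table, groups)
            for name, or_true in MARKER_ODDS_RATIOS.items():
                est = np.log(model.table.loc[name, "odds_ratio"])
                se = model.table.loc[name, "se"]
                total += 1
                ok += abs(est - np.log(or_true)) <= 3 * se
        assert ok / total >= 0.95


class TestCascade:
    def test_audit_complete_every_category_once_per_stage(
        self, small_cohort, small_features, fitted_small
    ):
        cohort, spec = small_cohort
        comparisons = tl.comparison_grid(small_features, fitted_small.assignment)
        cascade = run_marker_cascade(
            comparisons, small_features, fitted_small.assignment,
            tl.toy_lexicon(), n_folds=5, seed=3,
        )
        audit = cascade.audit
        # stage 1 covers every input category exactly once
        stage1 = audit[audit["stage"] == "significant"]
        assert sorted(stage1["category"]) == sorted(small_features.categories)
        # each later stage covers exactly the survivors of the previous
        sig_kept = set(stage1[stage1["reason"] == "kept"]["category"])
        stage2 = audit[audit["stage"] == "hierarchy_pruned"]
        assert set(stage2["category"]) == sig_kept
        stage2_kept = set(stage2[stage2["reason"] == "kept"]["category"])
        stage3 = audit[audit["stage"] == "lasso_kept"]
        assert set(stage3["category"]) == stage2_kept
        # cardinality never increases along the cascade
        assert len(sig_kept) >= len(stage2_kept) >= len(cascade.model.table)

    def test_parents_pruned_before_model(
        self, small_cohort, small_features, fitted_small
    ):
        comparisons = tl.comparison_grid(small_features, fitted_small.assignment)
        cascade = run_marker_cascade(
            comparisons, small_features, fitted_small.assignment,
            tl.toy_lexicon(), n_folds=5, seed=3,
        )
        final = set(cascade.model.table.index)
        # no surviving marker is an ancestor of another survivor
        lex = tl.toy_lexicon()
        for cat in final:
            assert not (lex.ancestors(cat) & final - {cat})
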