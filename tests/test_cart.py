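"""Classification tree: Gini splitting, recursion, accuracy on the fixture."""

import numpy as np
import pandas as pd
import pytest

from riskitems.cart import (
    CartParams,
    best_split,
    fit_tree,
    gini_impurity,
    predict_tree,
    render_tree,
    tree_accuracy,
    tree_from_dict,
    tree_to_dict,
)
from riskitems.errors import ConfigurationError, DegenerateInputError

FIXTURE_ITEMS = [
    "lifetime_history_self_harm",
    "prior_psychiatric_treatment",
    "prev_attempt_or_psych_care",
    "benzodiazepines",
    "rational_thinking_loss",
]


def exhaustive_best_split(items: pd.DataFrame, outcomes, candidates):
    """Independent oracle: evaluate the Gini decrease of every candidate."""
    y = np.asarray(outcomes)
    best = None
    for item in candidates:
        keep = items[item].notna().to_numpy()
        x = items[item][keep].astype(int).to_numpy()
        yk = y[keep]
        if len(set(x)) < 2:
            continue
        def g(v):
            p = v.mean()
            return 1 - p * p - (1 - p) * (1 - p)
        dec = g(yk) - (
            (x == 0).sum() * g(yk[x == 0]) + (x == 1).sum() * g(yk[x == 1])
        ) / len(yk)
        if dec > 1e-12 and (best is None or dec > best[1] + 1e-12):
            best = (item, dec)
    return best


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "n_pos,n,expected", [(50, 100, 0.5), (0, 100, 0.0), (100, 100, 0.0), (30, 100, 0.42)]
    )
    def test_values(self, n_pos, n, expected):
        assert gini_impurity(n_pos, n) == pytest.approx(expected)

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            gini_impurity(0, 0)
        with pytest.raises(ValueError):
            gini_impurity(5, 4)


class TestBestSplit:
    def test_perfect_item_recovers_parent_impurity(self):
        items = pd.DataFrame({"perfect": [1, 1, 1, 0, 0, 0], "noise": [1, 0, 1, 0, 1, 0]})
        y = pd.Series([1, 1, 1, 0, 0, 0])
        item, dec = best_split(items, y, ["noise", "perfect"])
        assert item == "perfect"
        assert dec == pytest.approx(gini_impurity(3, 6))

    def test_fixture_root_split_is_prior_psychiatric_treatment(self, fixture_table):
        items = fixture_table[FIXTURE_ITEMS]
        found = best_split(items, fixture_table["outcome"], FIXTURE_ITEMS)
        oracle = exhaustive_best_split(items, fixture_table["outcome"], FIXTURE_ITEMS)
        assert found[0] == "prior_psychiatric_treatment"
        assert found == pytest.approx(oracle)

    def test_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(12, 60))
            k = int(rng.integers(2, 6))
            items = pd.DataFrame(
                {f"i{j}": rng.integers(0, 2, size=n) for j in range(k)}
            ).astype("Int64")
            y = pd.Series(rng.integers(0, 2, size=n))
            if y.sum() in (0, n):
                continue
            assert best_split(items, y, list(items.columns)) == exhaustive_best_split(
                items, y, list(items.columns)
            )

    def test_no_variation_returns_none(self):
        items = pd.DataFrame({"flat": [1, 1, 1, 1]})
        assert best_split(items, pd.Series([1, 0, 1, 0]), ["flat"]) is None

    def test_missing_rows_excluded_at_split(self):
        items = pd.DataFrame({"a": pd.array([1, 1, None, 0, 0, None], dtype="Int64")})
        y = pd.Series([1, 1, 1, 0, 0, 0])
        item, dec = best_split(items, y, ["a"])
        assert item == "a" and dec == pytest.approx(0.5)  # pure split on observed rows

    def test_weighted_child_impurity_never_exceeds_parent(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            items = pd.DataFrame({"x": rng.integers(0, 2, size=n)}).astype("Int64")
            y = pd.Series(rng.integers(0, 2, size=n))
            found = best_split(items, y, ["x"])
            if found is not None:
                assert found[1] >= 0


class TestFitTree:
    def test_constant_outcome_single_leaf(self):
        table = pd.DataFrame({"outcome": [0, 0, 0], "x": [0, 1, 0]})
        tree = fit_tree(table, ["x"])
        assert tree.is_leaf and tree.prediction == "low"

    def test_perfect_item_stops_at_depth_one(self):
        table = pd.DataFrame(
            {"outcome": [1, 1, 0, 0], "a": [1, 1, 0, 0], "b": [1, 1, 0, 0]}
        )
        tree = fit_tree(table, ["a", "b"])
        assert tree.split_item == "a"
        assert tree.left.is_leaf and tree.right.is_leaf

    def test_depth_limit_one_equals_root_item_classification(self, fixture_table):
        tree = fit_tree(fixture_table, FIXTURE_ITEMS, params=CartParams(max_depth=1))
        pred = predict_tree(tree, fixture_table)
        expected = fixture_table["prior_psychiatric_treatment"].map({1: "high", 0: "low"})
        assert (pred["prediction"] == expected).all()

    def test_terminates_without_limits_and_children_sum(self, fixture_table):
        tree = fit_tree(fixture_table, FIXTURE_ITEMS)

        def check(node):
            if node.split_item is None:
                return
            assert node.left.n + node.right.n == node.n  # no missing in fixture
            assert node.n_positive == node.left.n_positive + node.right.n_positive
            check(node.left)
            check(node.right)

        check(tree)

    def test_min_node_size_blocks_tiny_children(self):
        table = pd.DataFrame({"outcome": [1, 0, 0, 0, 0], "x": [1, 0, 0, 0, 0]})
        tree = fit_tree(table, ["x"], params=CartParams(min_node_size=2))
        assert tree.is_leaf

    def test_invalid_params(self):
        with pytest.raises(ConfigurationError):
            CartParams(criterion="entropy")
        with pytest.raises(ConfigurationError):
            CartParams(min_node_size=0)
        with pytest.raises(ConfigurationError):
            CartParams(classify="plurality")


class TestTreeAccuracy:
    def test_depth_one_fixture_tree_matches_published_statistics(self, fixture_table):
        tree = fit_tree(fixture_table, FIXTURE_ITEMS, params=CartParams(max_depth=1))
        acc, auc = tree_accuracy(tree, fixture_table)
        assert round(100 * acc.sensitivity, 1) == 85.5
        assert round(100 * acc.specificity, 1) == 45.3
        assert round(auc.auc, 2) == 0.65

    def test_single_leaf_tree_has_chance_auc(self, fixture_table):
        tree = fit_tree(fixture_table, FIXTURE_ITEMS, params=CartParams(max_depth=0))
        acc, auc = tree_accuracy(tree, fixture_table)
        assert auc.auc == 0.5
        assert acc.sensitivity == 1.0 and acc.specificity == 0.0  # leaf at prevalence -> high

    def test_perfect_item_gives_perfect_auc(self):
        table = pd.DataFrame({"outcome": [1, 1, 0, 0, 1, 0], "a": [1, 1, 0, 0, 1, 0]})
        tree = fit_tree(table, ["a"])
        _, auc = tree_accuracy(tree, table)
        assert auc.auc == 1.0

    def test_majority_rule_labels_minority_prevalence_leaves_low(self, fixture_table):
        tree = fit_tree(
            fixture_table,
            FIXTURE_ITEMS,
            params=CartParams(max_depth=1, classify="majority"),
        )
        # at 30% prevalence both leaves are majority-negative
        assert tree.left.prediction == "low" and tree.right.prediction == "low"

    def test_schema_mismatch_rejected(self, fixture_table):
        tree = fit_tree(fixture_table, FIXTURE_ITEMS, params=CartParams(max_depth=1))
        with pytest.raises(ConfigurationError):
            predict_tree(tree, fixture_table.drop(columns=["prior_psychiatric_treatment"]))


class TestSerialization:
    def test_dict_roundtrip_preserves_predictions(self, fixture_table):
        tree = fit_tree(fixture_table, FIXTURE_ITEMS, params=CartParams(max_depth=2))
        clone = tree_from_dict(tree_to_dict(tree))
        pd.testing.assert_frame_equal(
            predict_tree(tree, fixture_table), predict_tree(clone, fixture_table)
        )

    def test_render_mentions_root_split(self, fixture_table):
        tree = fit_tree(fixture_table, FIXTURE_ITEMS, params=CartParams(max_depth=1))
        text = render_tree(tree)
        assert "prior_psychiatric_treatment" in text and "n=483" in text
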