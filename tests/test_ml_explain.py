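import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from domtrace.descriptors import describe
from domtrace.ml_explain import (
    FEATURE_COLUMNS,
    AttributionMatrix,
    ModelConfig,
    attribute,
    build_labels,
    dependence_surface,
    global_importance,
    train,
)
from domtrace.synthetic_data import SyntheticConfig, plant_fate_rule, sample_formula_pool

QUICK = dict(
    learning_rates=(0.1, 0.3),
    max_depths=(3, 5),
    min_child_weights=(1,),
    k_folds=5,
    n_estimators=150,
)

FATE_NAMES = np.array(["removed", "resistant", "produced"])


@pytest.fixture(scope="module")
def planted():
    """Described pool with a planted logistic fate rule on (O/C, NOSC)."""
    pool = sample_formula_pool(SyntheticConfig(seed=17, n_formulas=2500))
    recs = describe(pool)
    labels, bayes = plant_fate_rule(recs, seed=17)
    recs = recs.assign(fate=FATE_NAMES[labels])
    return recs, bayes


@pytest.fixture(scope="module")
def trained(planted):
    recs, bayes = planted
    table = build_labels(recs, "fate")
    model, report = train(table, ModelConfig(seed=17, **QUICK))
    return table, model, report, bayes


class TestBuildLabels:
    def test_fate_dimension_codes(self, planted):
        recs, _ = planted
        table = build_labels(recs, "fate")
        assert list(table.columns) == list(FEATURE_COLUMNS) + ["label"]
        assert set(table["label"]) == {0, 1, 2}
        assert len(table) == len(recs)
        assert not table.isna().any().any()

    def test_elemental_dimension_drops_chons(self, planted):
        recs, _ = planted
        table = build_labels(recs, "elemental")
        kept = (recs["elemental_class"] != "CHONS").sum()
        assert len(table) == kept

    def test_category_dimension_drops_other_classes(self, planted):
        recs, _ = planted
        table = build_labels(recs, "category")
        kept = recs["compound_class"].isin(
            ["lignins/CRAM", "tannins", "aromatic"]
        ).sum()
        assert len(table) == kept

    def test_single_class_rejected(self, planted):
        recs, _ = planted
        solo = recs[recs["fate"] == "removed"]
        with pytest.raises(ValueError):
            build_labels(solo, "fate")


class TestTrain:
    def test_recovers_planted_rule_near_bayes(self, trained):
        _, _, report, bayes = trained
        assert report.test_accuracy >= 0.9 * bayes

    def test_cv_report_structure(self, trained):
        _, _, report, _ = trained
        assert len(report.grid_losses) == 4
        assert report.best_params in [
            {k: g[k] for k in ("learning_rate", "max_depth", "min_child_weight")}
            for g in report.grid_losses
        ]
        best = min(g["mean_cv_log_loss"] for g in report.grid_losses)
        assert report.test_log_loss > 0
        assert best == min(g["mean_cv_log_loss"] for g in report.grid_losses)

    def test_permuted_labels_fall_to_chance(self, planted):
        """With class-balanced, permuted labels no feature carries signal and
        held-out accuracy must fall to the 1/3 chance level."""
        recs, _ = planted
        table = build_labels(recs, "fate")
        rng = np.random.default_rng(0)
        # balance classes so the chance level is exactly 1/3, then permute
        per_class = table.groupby("label").size().min()
        table = pd.concat(
            [g.iloc[:per_class] for _, g in table.groupby("label")]
        ).reset_index(drop=True)
        table = table.assign(label=rng.permutation(table["label"].to_numpy()))
        _, report = train(
            table,
            ModelConfig(seed=17, learning_rates=(0.1,), max_depths=(3,),
                        min_child_weights=(1,), k_folds=5, n_estimators=100),
        )
        assert abs(report.test_accuracy - 1 / 3) <= 0.05

    def test_deterministic_under_seed(self, planted):
        recs, _ = planted
        table = build_labels(recs.iloc[:600], "fate")
        cfg = ModelConfig(seed=3, learning_rates=(0.3,), max_depths=(3,),
                          min_child_weights=(1,), k_folds=3, n_estimators=60)
        _, r1 = train(table, cfg)
        _, r2 = train(table, cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_too_few_rows_rejected(self, planted):
        recs, _ = planted
        with pytest.raises(ValueError):
            train(build_labels(recs, "fate").iloc[:30], ModelConfig(seed=1))


class TestAttribute:
    def test_additivity_margin_space(self, trained):
        table, model, _, _ = trained
        attr = attribute(model, table)
        assert attr.additivity_error() <= 1e-5

    def test_planted_drivers_carry_most_attribution(self, trained):
        table, model, _, _ = trained
        attr = attribute(model, table)
        imp = global_importance(attr)
        top2 = set(imp.index[:2])
        assert top2 == {"o_c", "nosc"}
        # each planted driver clearly dominates every other feature; some
        # attribution leaks into correlated encodings of the drivers (nO, nC)
        strongest_other = imp.drop(["o_c", "nosc"]).max()
        assert imp["o_c"] >= 3 * strongest_other
        assert imp["nosc"] >= 3 * strongest_other
        assert imp[["o_c", "nosc"]].sum() / imp.sum() >= 0.7

    def test_schema_mismatch_rejected(self, trained):
        _, model, _, _ = trained
        with pytest.raises(KeyError):
            attribute(model, pd.DataFrame({"o_c": [0.1]}))

    def test_stump_attribution_matches_closed_form(self):
        """Exact Shapley for a depth-1 single tree: phi = leaf value minus the
        cover-weighted mean leaf value; all other features get zero."""
        rng = np.random.default_rng(4)
        n = 400
        table = pd.DataFrame(
            {c: np.zeros(n) for c in FEATURE_COLUMNS} | {"o_c": rng.uniform(0, 1, n)}
        )
        y = (table["o_c"] > 0.5).astype(int) + (table["o_c"] > 0.8).astype(int)
        model = xgb.XGBClassifier(
            objective="multi:softprob", num_class=3, n_estimators=1, max_depth=1,
            learning_rate=1.0, random_state=0, n_jobs=1, tree_method="hist",
        )
        model.fit(table[list(FEATURE_COLUMNS)].to_numpy(float), y)
        attr = attribute(model, table)
        j = attr.feature_names.index("o_c")
        other = np.delete(attr.values, j, axis=2)
        assert np.abs(other).max() == 0.0
        # closed form per class from the dumped tree structure
        trees = model.get_booster().trees_to_dataframe()
        X = table[list(FEATURE_COLUMNS)].to_numpy(float)
        for cls in range(3):
            t = trees[trees["Tree"] == cls]
            if (t["Feature"] == "Leaf").all():
                expected = np.zeros(n)
            else:
                split = t[t["Feature"] != "Leaf"].iloc[0]["Split"]
                leaves = t[t["Feature"] == "Leaf"]
                vals = leaves["Gain"].to_numpy()
                cover = leaves["Cover"].to_numpy()
                mean_val = np.average(vals, weights=cover)
                # xgboost evaluates the split in float32
                left = X[:, j].astype(np.float32) < np.float32(split)
                expected = np.where(left, vals[0], vals[1]) - mean_val
            np.testing.assert_allclose(
                attr.values[:, cls, j], expected, atol=1e-5
            )


class TestDependenceSurface:
    def test_points_and_grid_shapes(self, trained):
        table, model, _, _ = trained
        attr = attribute(model, table)
        points, grid = dependence_surface(attr, table, "o_c", "nosc", class_id=2)
        assert len(points) == len(table)
        assert grid.shape == (20, 20)

    def test_produced_class_attribution_increases_with_oc(self, trained):
        """The planted rule makes high-O/C formulas 'produced'; the mean
        attribution of o_c to the produced class must rise along o_c."""
        table, model, _, _ = trained
        attr = attribute(model, table)
        points, _ = dependence_surface(attr, table, "o_c", "nosc", class_id=2)
        binned = points.groupby(pd.qcut(points["o_c"], 5, duplicates="drop"),
                                observed=True)["attribution"].mean()
        assert binned.iloc[-1] > binned.iloc[0]
        assert binned.is_monotonic_increasing

    def test_unused_feature_has_zero_column(self, trained):
        table, model, _, _ = trained
        attr = attribute(model, table)
        # at least verify: any feature with zero importance is exactly zero
        imp = np.abs(attr.values).mean(axis=(0, 1))
        for j, v in enumerate(imp):
            if v == 0:
                assert np.all(attr.values[:, :, j] == 0)

    def test_unknown_feature_rejected(self, trained):
        table, model, _, _ = trained
        attr = attribute(model, table)
        with pytest.raises(KeyError):
            dependence_surface(attr, table, "bogus", "nosc", 0)
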