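"""Gradient-boosted fate classification with Shapley-value interpretation.

A three-class XGBoost model predicts a formula's label (thermal fate,
elemental class, or compound category) from 12 molecular descriptors.
Hyperparameters (learning rate, maximum tree depth, minimum child weight)
are tuned by grid search with stratified k-fold cross-validation minimizing
multinomial log loss; the refit model is evaluated on a stratified held-out
split.  Interpretation uses exact tree-path Shapley attributions computed in
margin (pre-softmax) space, so per-sample attributions plus the class base
value reproduce the model output exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import accuracy_score, log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "FEATURE_COLUMNS",
    "ModelConfig",
    "CVReport",
    "AttributionMatrix",
    "build_labels",
    "train",
    "attribute",
    "global_importance",
    "dependence_surface",
]

#: The 12 descriptor features, in canonical column order.
FEATURE_COLUMNS = (
    "o_c",
    "h_c",
    "nosc",
    "ai_mod",
    "mw",
    "dbe",
    "dbe_minus_o_over_c",
    "nC",
    "nH",
    "nN",
    "nO",
    "nS",
)

_FATE_CODES = {"removed": 0, "resistant": 1, "produced": 2}
_ELEMENTAL_KEEP = ("CHO", "CHON", "CHOS")
_CATEGORY_KEEP = ("lignins/CRAM", "tannins", "aromatic")


@dataclass(frozen=True)
class ModelConfig:
    """Grid-search and training settings.

    The default grid spans learning rate {0.05, 0.1, 0.3}, depth {3, 5, 7}
    and minimum child weight {1, 3, 5} with 300 trees and 10-fold CV; pass a
    smaller grid for quick runs.
    """

    learning_rates: tuple[float, ...] = (0.05, 0.1, 0.3)
    max_depths: tuple[int, ...] = (3, 5, 7)
    min_child_weights: tuple[int, ...] = (1, 3, 5)
    k_folds: int = 10
    n_estimators: int = 300
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (self.learning_rates and self.max_depths and self.min_child_weights):
            raise ValueError("empty hyperparameter grid")

    @property
    def grid(self) -> list[dict]:
        return [
            {"learning_rate": lr, "max_depth": d, "min_child_weight": w}
            for lr, d, w in itertools.product(
                self.learning_rates, self.max_depths, self.min_child_weights
            )
        ]


@dataclass
class CVReport:
    """Grid-search outcome and held-out performance."""

    grid_losses: list[dict]
    best_params: dict
    test_accuracy: float
    test_log_loss: float
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "grid_losses": self.grid_losses,
            "best_params": self.best_params,
            "test_accuracy": self.test_accuracy,
            "test_log_loss": self.test_log_loss,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def build_labels(records: pd.DataFrame, dimension: str = "fate") -> pd.DataFrame:
    """Feature table with a 0/1/2 ``label`` column from described records.

    ``records`` must carry the descriptor columns plus ``fate`` (for the
    fate dimension), ``elemental_class`` or ``compound_class``.  The
    elemental dimension keeps CHO/CHON/CHOS; the category dimension keeps
    lignins-CRAM/tannins/aromatic; other rows are dropped.
    """
    df = records.copy()
    if dimension == "fate":
        if "fate" not in df:
            raise KeyError("records need a 'fate' column for the fate dimension")
        df["label"] = df["fate"].map(_FATE_CODES)
    elif dimension == "elemental":
        df = df[df["elemental_class"].isin(_ELEMENTAL_KEEP)]
        df["label"] = df["elemental_class"].map(
            {k: i for i, k in enumerate(_ELEMENTAL_KEEP)}
        )
    elif dimension == "category":
        df = df[df["compound_class"].isin(_CATEGORY_KEEP)]
        df["label"] = df["compound_class"].map(
            {k: i for i, k in enumerate(_CATEGORY_KEEP)}
        )
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    if df["label"].isna().any():
        raise ValueError("unmapped label values")
    out = pd.DataFrame(
        {
            "o_c": df["o_c"],
            "h_c": df["h_c"],
            "nosc": df["nosc"],
            "ai_mod": df["ai_mod"],
            "mw": df["mw"],
            "dbe": df["dbe"],
            "dbe_minus_o_over_c": df["dbe_minus_o_over_c"],
            "nC": df["c"],
            "nH": df["h"],
            "nN": df["n"],
            "nO": df["o"],
            "nS": df["s"],
            "label": df["label"].astype(int),
        }
    ).reset_index(drop=True)
    if out["label"].nunique() < 2:
        raise ValueError(f"dimension {dimension!r} yields fewer than 2 classes")
    return out


def _make_model(params: dict, config: ModelConfig, n_classes: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        objective="multi:softprob",
        num_class=n_classes,
        eval_metric="mlogloss",
        n_estimators=config.n_estimators,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        **params,
    )


def train(table: pd.DataFrame, config: ModelConfig) -> tuple[xgb.XGBClassifier, CVReport]:
    """Grid-searched, cross-validated training with a held-out evaluation.

    The table is split into stratified train/test portions; every grid
    point is scored by mean CV multinomial log loss on the training portion;
    the best configuration is refit on the full training portion and scored
    on the held-out split.  Deterministic under a fixed config seed.
    """
    if len(table) < 50:
        raise ValueError("need at least 50 rows to train")
    X = table[list(FEATURE_COLUMNS)].to_numpy(float)
    y = table["label"].to_numpy(int)
    classes = np.unique(y)
    n_classes = len(classes)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.test_fraction, stratify=y, random_state=config.seed
    )
    if np.min(np.bincount(y_tr)) < config.k_folds:
        raise ValueError(
            "a class has fewer members than k_folds; reduce k or rebalance"
        )
    skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X_tr, y_tr))
    grid_losses: list[dict] = []
    best_loss, best_params = np.inf, None
    for params in config.grid:
        losses = []
        for tr_idx, va_idx in folds:
            model = _make_model(params, config, n_classes)
            model.fit(X_tr[tr_idx], y_tr[tr_idx])
            proba = model.predict_proba(X_tr[va_idx])
            losses.append(log_loss(y_tr[va_idx], proba, labels=classes))
        mean_loss = float(np.mean(losses))
        grid_losses.append({**params, "mean_cv_log_loss": mean_loss})
        if mean_loss < best_loss:
            best_loss, best_params = mean_loss, params
    model = _make_model(best_params, config, n_classes)
    model.fit(X_tr, y_tr)
    proba_te = model.predict_proba(X_te)
    report = CVReport(
        grid_losses=grid_losses,
        best_params=dict(best_params),
        test_accuracy=float(accuracy_score(y_te, model.predict(X_te))),
        test_log_loss=float(log_loss(y_te, proba_te, labels=classes)),
        n_train=len(y_tr),
        n_test=len(y_te),
    )
    return model, report


@dataclass
class AttributionMatrix:
    """Exact tree-path Shapley attributions in margin space.

    ``values[i, c, j]`` is the attribution of feature j to class c's margin
    for sample i; ``base[c]`` is the class base value.  For every sample and
    class, base + Σⱼ values equals the model's margin output.
    """

    values: np.ndarray  # (n_samples, n_classes, n_features)
    base: np.ndarray  # (n_classes,)
    feature_names: tuple[str, ...]
    margins: np.ndarray  # (n_samples, n_classes)

    def additivity_error(self) -> float:
        """Max relative additivity violation over samples and classes."""
        total = self.values.sum(axis=2) + self.base[None, :]
        return float(
            np.max(np.abs(total - self.margins) / (1.0 + np.abs(self.margins)))
        )

    def to_frame(self) -> pd.DataFrame:
        n, k, p = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n), range(k), self.feature_names],
            names=["sample", "class", "feature"],
        )
        return pd.DataFrame(
            {"attribution": self.values.reshape(-1)}, index=idx
        ).reset_index()


def _float64_margins(booster: xgb.Booster, dm: xgb.DMatrix, n_classes: int) -> np.ndarray:
    """Margin output re-accumulated in float64.

    The native margin prediction sums leaf values in float32, which after a
    few hundred trees carries ~1e-6 rounding noise — enough to obscure the
    exact additivity of tree-path Shapley values.  Summing the visited leaf
    values (from the model dump) in float64 gives a clean reference.
    """
    leaf_idx = booster.predict(dm, pred_leaf=True).astype(int)
    if leaf_idx.ndim == 1:
        leaf_idx = leaf_idx[:, None]
    if leaf_idx.ndim == 3:  # (n, rounds, classes) in some versions
        leaf_idx = leaf_idx.reshape(leaf_idx.shape[0], -1)
    trees = booster.trees_to_dataframe()
    n_trees = leaf_idx.shape[1]
    value_maps: list[np.ndarray] = []
    for t in range(n_trees):
        sub = trees[trees["Tree"] == t]
        vm = np.zeros(int(sub["Node"].max()) + 1)
        leaves = sub[sub["Feature"] == "Leaf"]
        vm[leaves["Node"].to_numpy(int)] = leaves["Gain"].to_numpy(np.float64)
        value_maps.append(vm)
    n = leaf_idx.shape[0]
    margins = np.zeros((n, n_classes))
    for t in range(n_trees):
        margins[:, t % n_classes] += value_maps[t][leaf_idx[:, t]]
    # per-class intercept (constant); recovered against the float32 margin
    m32 = booster.predict(dm, output_margin=True).astype(np.float64)
    if m32.ndim == 1:
        m32 = m32[:, None]
    margins += np.mean(m32 - margins, axis=0, keepdims=True)
    return margins


def attribute(model: xgb.XGBClassifier, table: pd.DataFrame) -> AttributionMatrix:
    """Shapley attributions of the model on a feature table (margin space)."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"feature table missing columns {missing}")
    X = table[list(FEATURE_COLUMNS)].to_numpy(float)
    booster = model.get_booster()
    dm = xgb.DMatrix(X, feature_names=list(FEATURE_COLUMNS))
    contrib = booster.predict(dm, pred_contribs=True).astype(np.float64)
    n_classes = contrib.shape[1] if contrib.ndim == 3 else 1
    # Tree-path Shapley values are additive over trees; accumulating the
    # per-round contributions in float64 (instead of the native float32
    # running sum over hundreds of trees) keeps additivity exact to ~1e-7.
    n_rounds = booster.num_boosted_rounds()
    acc = np.zeros_like(contrib)
    for r in range(n_rounds):
        part = booster[r : r + 1].predict(dm, pred_contribs=True)
        if part.ndim == 2:
            part = part[:, None, :]
        acc += part.astype(np.float64)
    base = contrib[0, :, -1].copy() if contrib.ndim == 3 else np.array([contrib[0, -1]])
    if contrib.ndim == 2:
        contrib = contrib[:, None, :]
    contrib = np.concatenate(
        [acc[:, :, :-1], np.broadcast_to(base[None, :, None], (len(X), n_classes, 1))],
        axis=2,
    )
    margins = _float64_margins(booster, dm, n_classes)
    return AttributionMatrix(
        values=contrib[:, :, :-1],
        base=contrib[0, :, -1].copy(),
        feature_names=tuple(FEATURE_COLUMNS),
        margins=margins,
    )


def global_importance(attr: AttributionMatrix) -> pd.Series:
    """Features ranked by mean |attribution| over samples and classes;
    ties broken alphabetically."""
    imp = np.abs(attr.values).mean(axis=(0, 1))
    s = pd.Series(imp, index=list(attr.feature_names), name="mean_abs_attribution")
    return s.sort_index().sort_values(ascending=False, kind="stable")


def dependence_surface(
    attr: AttributionMatrix,
    table: pd.DataFrame,
    feature_x: str,
    feature_color: str,
    class_id: int,
    n_grid: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample dependence triples and a binned-mean attribution grid.

    Returns (points, grid): ``points`` has one row per sample with the x
    feature value, the attribution of ``feature_x`` to ``class_id``, and the
    colouring feature value; ``grid`` is the n_grid × n_grid mean
    attribution over (feature_x, feature_color) bins (NaN for empty cells).
    """
    for f in (feature_x, feature_color):
        if f not in attr.feature_names:
            raise KeyError(f"unknown feature {f!r}")
    jx = attr.feature_names.index(feature_x)
    phi = attr.values[:, class_id, jx]
    x = table[feature_x].to_numpy(float)
    color = table[feature_color].to_numpy(float)
    points = pd.DataFrame(
        {feature_x: x, "attribution": phi, feature_color: color}
    )
    x_edges = np.linspace(x.min(), x.max(), n_grid + 1)
    c_edges = np.linspace(color.min(), color.max(), n_grid + 1)
    xi = np.clip(np.digitize(x, x_edges) - 1, 0, n_grid - 1)
    ci = np.clip(np.digitize(color, c_edges) - 1, 0, n_grid - 1)
    sums = np.zeros((n_grid, n_grid))
    cnts = np.zeros((n_grid, n_grid))
    np.add.at(sums, (xi, ci), phi)
    np.add.at(cnts, (xi, ci), 1)
    with np.errstate(invalid="ignore"):
        grid = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    grid_df = pd.DataFrame(
        grid,
        index=pd.Index(0.5 * (x_edges[:-1] + x_edges[1:]), name=feature_x),
        columns=pd.Index(0.5 * (c_edges[:-1] + c_edges[1:]), name=feature_color),
    )
    return points, grid_df
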