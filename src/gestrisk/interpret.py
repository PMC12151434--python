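"""Additive per-prediction feature attribution (Shapley-style).

Every attribution satisfies local accuracy: for each row,

    base_value + sum_j attribution_j = model output for that row

on the attribution scale.  The scale and method depend on the family:

* gradient boosting — exact path-dependent tree Shapley values on the
  margin (log-odds) scale, computed in double precision over the fitted
  trees (matching the booster's own float32 contributions to ~1e-5);
* random forest — the same tree-exact algorithm on the probability scale
  (the forest averages per-tree class probabilities);
* logistic / elastic net — closed-form linear Shapley values on the margin
  scale: ``coef_j * (z_j - mean(background z_j))`` after standardization,
  which is exact because the margin is additive in the inputs;
* all other families — a seeded permutation-sampling Shapley estimator on
  the probability scale.  The telescoping construction keeps additivity
  exact for any number of draws; only the per-feature split is approximate.

For the tree families the reference value is path-dependent (derived from
training-data node covers), so no background sample enters; for the other
methods the background is a seeded subsample of the development matrix.

"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logit

from ._treeshap import FlatTree, forest_expected_value, forest_predict, tree_shap
from .modeling import RiskModel, LINEAR_FAMILIES

__all__ = [
    "AttributionSet",
    "attribute",
    "model_output",
    "global_importance",
    "category_contributions",
]


@dataclass
class AttributionSet:
    values: pd.DataFrame            # rows x features
    base_value: float               # reference output on `scale`
    scale: str                      # "margin" or "probability"
    feature_categories: dict[str, str] = field(default_factory=dict)

    def local_accuracy_gap(self, outputs: np.ndarray) -> np.ndarray:
        """Per-row |base + sum(attributions) - output|."""
        total = self.base_value + self.values.sum(axis=1).to_numpy()
        return np.abs(total - np.asarray(outputs, dtype=float))


def _background_sample(background: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    if len(background) <= n:
        return background
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(background), size=n, replace=False)
    return background.iloc[rows]


def _flatten_xgb(model: RiskModel) -> tuple[list[FlatTree], float]:
    """Flatten a fitted booster into per-tree arrays plus the margin offset."""
    import json

    booster = model.estimator.get_booster()
    raw = json.loads(booster.save_raw("json"))
    trees = []
    for tr in raw["learner"]["gradient_booster"]["model"]["trees"]:
        cl = np.asarray(tr["left_children"], dtype=np.int64)
        cr = np.asarray(tr["right_children"], dtype=np.int64)
        ft = np.asarray(tr["split_indices"], dtype=np.int64)
        # split_conditions carries float32 thresholds on internal nodes and
        # the leaf output value on leaves; parse through float32 so the
        # comparisons reproduce the booster's routing exactly
        cond = np.asarray(tr["split_conditions"], dtype=np.float32).astype(np.float64)
        leaf = cl < 0
        th = np.where(leaf, 0.0, cond)
        vl = np.where(leaf, cond, 0.0)
        ft = np.where(leaf, -1, ft)
        cv = np.asarray(tr["sum_hessian"], dtype=np.float64)
        trees.append(FlatTree(cl, cr, ft, th, vl, cv))
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    objective = cfg["learner"]["objective"].get("name", "")
    # base_score is stored on the probability scale for logistic objectives
    offset = float(logit(base_score)) if "logistic" in objective else base_score
    return trees, offset


def _flatten_forest(model: RiskModel) -> list[FlatTree]:
    """Flatten a random forest; leaf values are per-tree case probabilities."""
    rf = model.estimator
    trees = []
    for est in rf.estimators_:
        t = est.tree_
        counts = t.value[:, 0, :]
        with np.errstate(invalid="ignore"):
            prob = counts[:, 1] / counts.sum(axis=1)
        vl = np.where(t.children_left < 0, prob, 0.0) / len(rf.estimators_)
        trees.append(FlatTree(
            t.children_left.astype(np.int64), t.children_right.astype(np.int64),
            t.feature.astype(np.int64), t.threshold.astype(np.float64),
            vl.astype(np.float64), t.weighted_n_node_samples.astype(np.float64),
        ))
    return trees


def _tree_inputs(model: RiskModel, X: pd.DataFrame) -> np.ndarray:
    # both tree backends cast inputs to float32 before routing; round the
    # same way so threshold comparisons match their traversal exactly
    arr = X.to_numpy(dtype=np.float64)
    return arr.astype(np.float32).astype(np.float64)


def _tree_attribution(model: RiskModel, X: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    if model.family == "gradient_boosting":
        trees, offset = _flatten_xgb(model)
        strict = True
    else:
        trees, offset = _flatten_forest(model), 0.0
        strict = False
    phi = tree_shap(trees, _tree_inputs(model, X), strict_less=strict)
    base = forest_expected_value(trees) + offset
    return pd.DataFrame(phi, index=X.index, columns=X.columns), base


def model_output(model: RiskModel, X: pd.DataFrame, scale: str) -> np.ndarray:
    """The model's output on the requested attribution scale.

    Margin outputs for the tree/linear families are evaluated in double
    precision (they agree with the estimator's own float32 outputs to
    float32 rounding); probability outputs come straight from the
    estimator.
    """
    if scale == "probability":
        return model.estimator.predict_proba(X)[:, 1]
    if model.family == "gradient_boosting":
        trees, offset = _flatten_xgb(model)
        return forest_predict(trees, _tree_inputs(model, X), True) + offset
    if model.family in LINEAR_FAMILIES:
        pipe = model.estimator
        z = pipe.named_steps["scale"].transform(X)
        clf = pipe.named_steps["clf"]
        return z @ clf.coef_[0] + clf.intercept_[0]
    raise ValueError(f"margin scale undefined for family {model.family!r}")


def _linear_attribution(model: RiskModel, X: pd.DataFrame,
                        background: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    pipe = model.estimator
    scaler, clf = pipe.named_steps["scale"], pipe.named_steps["clf"]
    z = scaler.transform(X)
    z_bg = scaler.transform(background).mean(axis=0)
    coef = clf.coef_[0]
    values = pd.DataFrame((z - z_bg) * coef, index=X.index, columns=X.columns)
    base = float(clf.intercept_[0] + coef @ z_bg)
    return values, base


def _sampled_attribution(model: RiskModel, X: pd.DataFrame, background: pd.DataFrame,
                         n_draws: int, seed: int) -> tuple[pd.DataFrame, float]:
    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    p = len(cols)
    bg = background.to_numpy(dtype=float)
    draws_bg = bg[rng.integers(0, len(bg), size=n_draws)]
    perms = np.stack([rng.permutation(p) for _ in range(n_draws)])

    def f(mat: np.ndarray) -> np.ndarray:
        return model.estimator.predict_proba(pd.DataFrame(mat, columns=cols))[:, 1]

    Xv = X.to_numpy(dtype=float)
    n = len(Xv)
    phi = np.zeros((n, p))
    base = float(f(draws_bg).mean())
    for d in range(n_draws):
        order = perms[d]
        current = np.tile(draws_bg[d], (n, 1))
        prev = f(current)
        for j in order:
            current[:, j] = Xv[:, j]
            cur = f(current)
            phi[:, j] += cur - prev
            prev = cur
    phi /= n_draws
    return pd.DataFrame(phi, index=X.index, columns=cols), base


def attribute(model: RiskModel, X: pd.DataFrame, background: pd.DataFrame,
              categories: Mapping[str, str] | None = None,
              n_background: int = 100, n_draws: int = 10,
              seed: int = 0) -> AttributionSet:
    """Attribute each prediction to its features; see module docstring."""
    if list(X.columns) != model.columns:
        raise ValueError("attribution matrix columns do not match training columns")
    if list(background.columns) != model.columns:
        raise ValueError("background columns do not match training columns")
    bg = _background_sample(background, n_background, seed)

    if model.family in ("gradient_boosting", "random_forest"):
        values, base = _tree_attribution(model, X)
        scale = "margin" if model.family == "gradient_boosting" else "probability"
    elif model.family in LINEAR_FAMILIES:
        values, base = _linear_attribution(model, X, bg)
        scale = "margin"
    else:
        values, base = _sampled_attribution(model, X, bg, n_draws, seed)
        scale = "probability"
    return AttributionSet(
        values=values,
        base_value=base,
        scale=scale,
        feature_categories=dict(categories or {}),
    )


def beeswarm(attributions: AttributionSet, X: pd.DataFrame, path,
             top: int = 12, seed: int = 0) -> None:
    """Beeswarm-style summary plot: one strip per top feature.

    Points are per-row attributions, jittered vertically and colored by the
    (rank-normalized) feature value. Requires matplotlib.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = global_importance(attributions).index[:top][::-1]
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(order) + 1.5))
    for i, feat in enumerate(order):
        vals = attributions.values[feat].to_numpy()
        raw = X[feat].to_numpy(dtype=float)
        color = pd.Series(raw).rank(pct=True).to_numpy()
        jitter = i + (rng.random(len(vals)) - 0.5) * 0.6
        ax.scatter(vals, jitter, c=color, cmap="coolwarm", s=8, alpha=0.7,
                   linewidths=0)
    ax.set_yticks(range(len(order)), order)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(f"attribution ({attributions.scale} scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def global_importance(attributions: AttributionSet) -> pd.Series:
    """Features ranked by mean |attribution|, ties broken by name."""
    if attributions.values.empty:
        raise ValueError("empty attribution set")
    mean_abs = attributions.values.abs().mean(axis=0)
    order = sorted(mean_abs.index, key=lambda c: (-mean_abs[c], c))
    return mean_abs.loc[order]


def category_contributions(per_timepoint: Mapping[float, AttributionSet]) -> pd.DataFrame:
    """Share of total mean |attribution| per feature category and timepoint.

    Shares sum to 1 at every timepoint; a feature without a category
    assignment is an error (the taxonomy must cover the model).
    """
    rows = {}
    for timepoint in sorted(per_timepoint):
        att = per_timepoint[timepoint]
        mean_abs = att.values.abs().mean(axis=0)
        shares: dict[str, float] = {}
        for feature, value in mean_abs.items():
            cat = att.feature_categories.get(feature)
            if cat is None:
                raise ValueError(f"feature {feature!r} has no category assignment")
            shares[cat] = shares.get(cat, 0.0) + float(value)
        total = sum(shares.values())
        rows[timepoint] = {c: (v / total if total > 0 else 0.0) for c, v in shares.items()}
    return pd.DataFrame(rows).T.fillna(0.0).sort_index()
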