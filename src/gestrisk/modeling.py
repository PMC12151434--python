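"""Model training: imbalance resampling, CV hyperparameter search, six families.

Preeclampsia is rare (~6% of pregnancies), so training data are rebalanced
before fitting.  Resampling is applied *inside* each cross-validation
training fold and never to validation folds or the test set — synthetic or
duplicated minority rows must not appear in any data a model is scored on.

Hyperparameters are chosen by seeded random search over a per-family space:
the family default is always candidate 0, ten candidates are evaluated by
5-fold stratified CV, and the candidate with the best mean validation AUC
wins (ties go to the earlier candidate).  The winner is then refit on the
full development matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .evaluation import concordance_auc

__all__ = [
    "FAMILIES",
    "RESAMPLERS",
    "ModelConfig",
    "RiskModel",
    "rebalance",
    "tune",
    "fit",
    "predict_risk",
    "train_all",
    "default_search_space",
]

FAMILIES = ("logistic", "elastic_net", "naive_bayes", "random_forest",
            "gradient_boosting", "mlp")
RESAMPLERS = ("random_over", "random_under", "smote", "borderline_smote", "none")

#: families whose matrix must be VIF-pruned before fitting
LINEAR_FAMILIES = ("logistic", "elastic_net")

_SEARCH_SPACES: dict[str, dict] = {
    "logistic": {"clf__C": ("loguniform", 1e-3, 1e2)},
    "elastic_net": {
        "clf__C": ("loguniform", 1e-3, 1e2),
        "clf__l1_ratio": ("uniform", 0.0, 1.0),
    },
    "naive_bayes": {"var_smoothing": ("loguniform", 1e-11, 1e-5)},
    "random_forest": {
        "n_estimators": ("int", 100, 300),
        "max_depth": [None, 4, 8, 16],
        "min_samples_leaf": ("int", 1, 20),
    },
    "gradient_boosting": {
        "n_estimators": ("int", 50, 200),
        "max_depth": ("int", 2, 6),
        "learning_rate": ("loguniform", 0.03, 0.3),
        "subsample": ("uniform", 0.6, 1.0),
    },
    "mlp": {
        "clf__hidden_layer_sizes": [(32,), (64,), (32, 16), (64, 32)],
        "clf__alpha": ("loguniform", 1e-5, 1e-1),
        "clf__learning_rate_init": ("loguniform", 1e-4, 1e-2),
    },
}


def default_search_space(family: str) -> dict:
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    return dict(_SEARCH_SPACES[family])


@dataclass(frozen=True)
class ModelConfig:
    family: str
    resampler: str = "random_over"
    search_space: dict = field(default_factory=dict)
    cv_folds: int = 5
    search_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.resampler not in RESAMPLERS:
            raise ValueError(f"unknown resampler {self.resampler!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.search_iterations < 1:
            raise ValueError("search_iterations must be >= 1")

    def space(self) -> dict:
        return self.search_space or default_search_space(self.family)


@dataclass
class RiskModel:
    family: str
    estimator: object
    hyperparameters: dict
    columns: list[str]
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# resampling


def _check_binary(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("resampling requires both classes present")


def rebalance(X: pd.DataFrame, y, method: str, seed: int = 0):
    """Equalize class counts; see module docstring for the four schemes."""
    if method not in RESAMPLERS:
        raise ValueError(f"unknown resampler {method!r}")
    y = np.asarray(y, dtype=bool)
    if method == "none":
        return X, pd.Series(y, index=X.index)
    _check_binary(y)
    rng = np.random.default_rng(seed)
    idx_min = np.flatnonzero(y == (y.sum() <= (~y).sum()))
    idx_maj = np.flatnonzero(y != (y.sum() <= (~y).sum()))
    n_min, n_maj = len(idx_min), len(idx_maj)

    if method == "random_over":
        extra = rng.choice(idx_min, size=n_maj - n_min, replace=True)
        order = np.concatenate([np.arange(len(y)), extra])
        Xr = X.iloc[order].reset_index(drop=True)
        yr = pd.Series(y[order])
        return Xr, yr
    if method == "random_under":
        kept_maj = rng.choice(idx_maj, size=n_min, replace=False)
        order = np.sort(np.concatenate([idx_min, kept_maj]))
        return X.iloc[order].reset_index(drop=True), pd.Series(y[order])

    # SMOTE variants: synthesize minority rows by convex interpolation
    Xv = X.to_numpy(dtype=float)
    minority = Xv[idx_min]
    k = min(5, n_min - 1)
    if k < 1:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if method == "smote":
        seeds_pool = np.arange(n_min)
    else:  # borderline: minority points whose neighborhood is majority-heavy
        m = min(10, len(y) - 1)
        nn_all = NearestNeighbors(n_neighbors=m + 1).fit(Xv)
        _, nbrs = nn_all.kneighbors(minority)
        maj_frac = np.isin(nbrs[:, 1:], idx_maj).mean(axis=1)
        danger = np.flatnonzero((maj_frac >= 0.5) & (maj_frac < 1.0))
        seeds_pool = danger if len(danger) else np.arange(n_min)
    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, min_nbrs = nn_min.kneighbors(minority)
    n_new = n_maj - n_min
    picks = rng.choice(seeds_pool, size=n_new, replace=True)
    nbr_pick = min_nbrs[picks, 1 + rng.integers(0, k, size=n_new)]
    gaps = rng.random(n_new)[:, None]
    synth = minority[picks] + gaps * (minority[nbr_pick] - minority[picks])
    Xr = pd.DataFrame(np.vstack([Xv, synth]), columns=X.columns)
    yr = pd.Series(np.concatenate([y, np.ones(n_new, dtype=bool)]))
    return Xr, yr


# ---------------------------------------------------------------------------
# estimators


def _make_estimator(family: str, params: Mapping, seed: int):
    params = dict(params)
    if family == "logistic":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
        ])
    elif family == "elastic_net":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(solver="saga", l1_ratio=0.5,
                                       max_iter=3000, random_state=seed)),
        ])
    elif family == "naive_bayes":
        est = GaussianNB()
    elif family == "random_forest":
        est = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    elif family == "gradient_boosting":
        est = XGBClassifier(
            n_estimators=150, max_depth=4, learning_rate=0.1,
            tree_method="hist", n_jobs=1, random_state=seed,
            eval_metric="logloss",
        )
    elif family == "mlp":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(hidden_layer_sizes=(32,), max_iter=300,
                                  random_state=seed)),
        ])
    else:
        raise ValueError(f"unknown model family {family!r}")
    if params:
        est.set_params(**params)
    return est


def _draw_candidate(space: Mapping, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        if isinstance(spec, (list, tuple)) and spec and spec[0] == "loguniform":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif isinstance(spec, (list, tuple)) and spec and spec[0] == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif isinstance(spec, (list, tuple)) and spec and spec[0] == "int":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif isinstance(spec, (list, tuple)):
            out[name] = spec[int(rng.integers(0, len(spec)))]
        else:
            out[name] = spec
    return out


def tune(family: str, X: pd.DataFrame, y, config: ModelConfig) -> dict:
    """Best hyperparameters by mean CV AUC over seeded random candidates.

    Candidate 0 is always the family default (empty parameter dict).
    Resampling happens inside training folds only.
    """
    y = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(config.seed)
    space = config.space()
    candidates: list[dict] = [{}]
    candidates += [_draw_candidate(space, rng) for _ in range(config.search_iterations - 1)]

    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    for _, va in folds:
        if len(np.unique(y[va])) < 2:
            raise ValueError("degenerate CV fold: validation fold has one class")

    best, best_mean = None, -np.inf
    for cand in candidates:
        aucs = []
        for fold_i, (tr, va) in enumerate(folds):
            Xtr, ytr = rebalance(X.iloc[tr], y[tr], config.resampler,
                                 seed=config.seed + fold_i)
            est = _make_estimator(family, cand, seed=config.seed)
            est.fit(Xtr, np.asarray(ytr))
            scores = est.predict_proba(X.iloc[va])[:, 1]
            aucs.append(concordance_auc(y[va], scores))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_mean:  # strict: earlier candidate wins ties
            best, best_mean = cand, mean_auc
    return {"params": dict(best), "mean_cv_auc": best_mean}


def fit(family: str, hyperparameters: Mapping, X: pd.DataFrame, y,
        seed: int = 0, resampler: str = "random_over") -> RiskModel:
    """Refit on the full development matrix (rebalanced) with chosen params."""
    arr = X.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("feature matrix contains non-finite values; impute first")
    Xr, yr = rebalance(X, y, resampler, seed=seed)
    est = _make_estimator(family, hyperparameters, seed=seed)
    est.fit(Xr, np.asarray(yr))
    return RiskModel(
        family=family,
        estimator=est,
        hyperparameters=dict(hyperparameters),
        columns=list(X.columns),
        metadata={"seed": seed, "resampler": resampler, "n_train": int(len(X))},
    )


def predict_risk(model: RiskModel, X: pd.DataFrame) -> np.ndarray:
    """Probability of the case class; errors on column mismatch."""
    if list(X.columns) != model.columns:
        raise ValueError("prediction matrix columns do not match training columns")
    return model.estimator.predict_proba(X)[:, 1]


def train_all(
    datasets: Mapping[float, object],
    configs: Sequence[ModelConfig],
    dev_index: pd.Index | None = None,
    selector_factory=None,
) -> dict:
    """Tune and fit every (timepoint, family) pair.

    ``datasets`` maps timepoint -> CensoredDataset (uncut: dev/test rows
    together); ``dev_index`` restricts fitting to development pregnancies.
    Returns ``{"models": {(timepoint, family): RiskModel},
    "selectors": {timepoint: FeatureSelector}}``.
    """
    from .features import FeatureSelector

    registry: dict = {"models": {}, "selectors": {}}
    for timepoint in sorted(datasets):
        ds = datasets[timepoint]
        if dev_index is not None:
            rows = ds.X.index.intersection(dev_index)
        else:
            rows = ds.X.index
        X_dev, y_dev = ds.X.loc[rows], ds.y.loc[rows]
        selector = (selector_factory() if selector_factory else FeatureSelector())
        selector.fit(X_dev, y_dev)
        registry["selectors"][timepoint] = selector
        for config in configs:
            linear = config.family in LINEAR_FAMILIES
            Xd = selector.transform(X_dev, for_linear=linear)
            chosen = tune(config.family, Xd, y_dev, config)
            model = fit(config.family, chosen["params"], Xd, y_dev,
                        seed=config.seed, resampler=config.resampler)
            model.metadata.update(
                timepoint=timepoint,
                mean_cv_auc=chosen["mean_cv_auc"],
                for_linear=linear,
            )
            registry["models"][(timepoint, config.family)] = model
    return registry
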