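"""Feature engineering for gestational-age-censored event streams.

Each vital-sign and laboratory series is reduced to summary statistics
(mean, max, min, median, number of readings), the third-order c3 statistic
at lag 2, linear and quadratic trend coefficients from a polynomial fit on
times centered at the censor point, and — for blood pressure — per-bin
min/max/mean with deltas of means across consecutive bins, where the bins
are the censor-schedule prefix (e.g., at 28 weeks: [0,14), [14,20),
[20,24), [24,28) weeks).

The c3 statistic is the lag-spaced mean of triple products

    c3(x, lag) = (1 / (n - 2*lag)) * sum_t x[t + 2*lag] * x[t + lag] * x[t]

and captures third-order (beyond-linear) temporal structure; it is absent
when the series is shorter than 2*lag + 1.

Selection and imputation are strictly train/apply separated: missingness
cutoffs, medians, the univariate relevance filter (rank test with
Benjamini-Hochberg control at 0.05) and the iterative VIF pruning are all
fitted on the development split and replayed unchanged on any other matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureSpec",
    "RelevanceResult",
    "series_summary",
    "c3_statistic",
    "polynomial_trend",
    "bin_statistics",
    "relevance_filter",
    "impute_and_filter",
    "vif_prune",
    "FeaturePipeline",
    "FeatureSelector",
    "censor_bin_edges",
]

_MINUTES_PER_DAY = 1440

#: category taxonomy used by the attribution summaries
CATEGORIES = ("medical_history", "vital_signs", "laboratory", "demographics",
              "family_history", "other")

_VITAL_CODES = ("SBP", "DBP")
_LAB_CODES = ("AST", "ALT", "URIC_ACID", "RBC", "URINE_PROT")

_STATIC_CATEGORY = {
    "age_years": "demographics",
    "bmi_baseline": "demographics",
    "gravidity": "medical_history",
    "parity": "medical_history",
    "nulliparous": "medical_history",
    "ivf": "medical_history",
    "multiple_gestation": "medical_history",
    "chronic_htn": "medical_history",
    "prior_preeclampsia": "medical_history",
    "prior_gest_htn": "medical_history",
    "diabetes": "medical_history",
    "kidney_disease": "medical_history",
    "autoimmune_disease": "medical_history",
    "family_hx_htn": "family_history",
    "family_hx_preeclampsia": "family_history",
    "sociodemographic_risk": "other",
    "personal_history_factors": "other",
}


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    source_code: str  # e.g. SBP, or "static"
    transform: str
    category: str = "other"
    bin_edges: tuple[float, ...] | None = None


@dataclass
class RelevanceResult:
    table: pd.DataFrame  # columns: feature, p_value, p_adjusted, retained
    alpha: float = 0.05

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["retained"], "feature"].tolist()


# ---------------------------------------------------------------------------
# elementary transforms


def series_summary(values) -> dict[str, float]:
    """Mean/max/min/median/count; all but count absent on an empty series."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return {"mean": np.nan, "max": np.nan, "min": np.nan, "median": np.nan, "count": 0}
    return {
        "mean": float(arr.mean()),
        "max": float(arr.max()),
        "min": float(arr.min()),
        "median": float(np.median(arr)),
        "count": int(arr.size),
    }


def c3_statistic(values, lag: int = 2) -> float:
    """Lag-spaced mean of triple products; NaN when n <= 2*lag."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n <= 2 * lag:
        return float("nan")
    m = n - 2 * lag
    return float(np.sum(x[2 * lag:] * x[lag:lag + m] * x[:m]) / m)


def polynomial_trend(times, values, degree: int = 2) -> tuple[float, float]:
    """Least-squares linear and quadratic coefficients of value vs time.

    ``times`` should already be centered (the pipeline centers at the censor
    time, which decorrelates the two terms).  With fewer than three points
    the quadratic term is absent (degree-1 fallback); with fewer than two,
    both are absent.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        return (float("nan"), float("nan"))
    if t.size < 3 or degree < 2 or np.ptp(t) == 0:
        if np.ptp(t) == 0:
            return (float("nan"), float("nan"))
        b = np.polynomial.polynomial.polyfit(t, v, 1)
        return (float(b[1]), float("nan"))
    b = np.polynomial.polynomial.polyfit(t, v, 2)
    return (float(b[1]), float(b[2]))


def bin_statistics(times_days, values, edges_weeks) -> dict[str, float]:
    """Per-bin {min,max,mean} plus deltas of means between consecutive bins.

    ``edges_weeks`` are gestational-week cut points; bin i covers
    [edges[i], edges[i+1]) weeks.  Empty bins yield absent statistics and
    absent deltas.
    """
    edges = np.asarray(edges_weeks, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    t = np.asarray(times_days, dtype=float) / 7.0
    v = np.asarray(values, dtype=float)
    out: dict[str, float] = {}
    means = []
    for i in range(len(edges) - 1):
        mask = (t >= edges[i]) & (t < edges[i + 1])
        tag = f"bin{i + 1}"
        if mask.any():
            sel = v[mask]
            out[f"{tag}_min"] = float(sel.min())
            out[f"{tag}_max"] = float(sel.max())
            out[f"{tag}_mean"] = float(sel.mean())
            means.append(float(sel.mean()))
        else:
            out[f"{tag}_min"] = out[f"{tag}_max"] = out[f"{tag}_mean"] = np.nan
            means.append(np.nan)
    for i in range(1, len(means)):
        out[f"delta_mean_bin{i}to{i + 1}"] = means[i] - means[i - 1]
    return out


def censor_bin_edges(visit_weeks, timepoint_weeks) -> tuple[float, ...]:
    """Bin edges = [0] + the censor-schedule weeks up to the timepoint."""
    edges = [0.0] + [float(w) for w in visit_weeks if w <= timepoint_weeks]
    if edges[-1] != float(timepoint_weeks):
        edges.append(float(timepoint_weeks))
    return tuple(edges)


# ---------------------------------------------------------------------------
# selection / imputation


def relevance_filter(matrix: pd.DataFrame, labels, alpha: float = 0.05) -> RelevanceResult:
    """Univariate two-sample rank test per feature with BH adjustment.

    A feature is retained iff its adjusted p-value is below ``alpha``.
    Constant (or single-group) features get p = 1 and are dropped.
    """
    y = np.asarray(labels, dtype=bool)
    pvals = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        a, b = x[ok & y], x[ok & ~y]
        if a.size == 0 or b.size == 0 or np.ptp(x[ok]) == 0:
            pvals.append(1.0)
            continue
        try:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        except ValueError:
            p = 1.0
        pvals.append(float(p) if np.isfinite(p) else 1.0)
    pvals = np.asarray(pvals)
    if len(pvals):
        retained, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")[:4]
    else:
        retained, p_adj = np.zeros(0, dtype=bool), pvals
    table = pd.DataFrame(
        {"feature": matrix.columns, "p_value": pvals, "p_adjusted": p_adj, "retained": retained}
    )
    return RelevanceResult(table=table, alpha=alpha)


def impute_and_filter(
    train_matrix: pd.DataFrame,
    apply_matrix: pd.DataFrame | None = None,
    missingness_threshold: float = 0.95,
):
    """Drop mostly-missing columns and median-impute from training statistics.

    Columns missing in more than ``missingness_threshold`` of training rows
    are removed from both matrices; remaining gaps are filled with the
    *training* column median.  Returns ``(train, apply, medians)`` with
    ``apply`` None when not supplied.
    """
    miss = train_matrix.isna().mean()
    keep = miss.index[miss <= missingness_threshold]
    train = train_matrix[keep].copy()
    medians = train.median()
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"cannot impute all-missing surviving columns: {bad}")
    train = train.fillna(medians)
    applied = None
    if apply_matrix is not None:
        applied = apply_matrix[keep].fillna(medians).copy()
    return train, applied, medians


def _vif_values(R: np.ndarray) -> np.ndarray:
    """VIFs as the diagonal of the inverse correlation matrix.

    Columns participating in an (almost) exactly collinear set get +inf.
    """
    p = R.shape[0]
    if p < 2:
        return np.ones(p)
    w, V = np.linalg.eigh(R)
    vif = np.full(p, np.inf)
    degenerate = w < 1e-10
    if degenerate.any():
        in_null = np.abs(V[:, degenerate]).max(axis=1) > 1e-8
        Rinv = np.linalg.pinv(R, hermitian=True)
        finite = np.maximum(np.diag(Rinv), 1.0)
        vif[~in_null] = finite[~in_null]
        return vif
    Rinv = (V / w) @ V.T
    return np.maximum(np.diag(Rinv), 1.0)


def vif_prune(matrix: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the worst-collinearity column until all VIF < threshold.

    Zero-variance columns are collinear with the intercept and are dropped
    first.  Ties on the maximum VIF are broken by dropping the
    lexicographically last column name, so the result is deterministic.
    Returns the retained column names in original order.
    """
    cols = list(matrix.columns)
    if len(cols) < 2:
        return cols
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = [c for c, s in zip(cols, sd) if s > 0]
    Xs = (X[:, [cols.index(c) for c in keep]] - X[:, [cols.index(c) for c in keep]].mean(axis=0))
    Xs /= Xs.std(axis=0)
    R_full = (Xs.T @ Xs) / len(Xs)
    idx = {c: i for i, c in enumerate(keep)}
    retained = list(keep)
    while len(retained) >= 2:
        sel = [idx[c] for c in retained]
        vifs = _vif_values(R_full[np.ix_(sel, sel)])
        worst = np.max(vifs)
        if worst < threshold:
            break
        ties = [retained[i] for i in np.flatnonzero(vifs == worst)]
        retained.remove(sorted(ties)[-1])
    return [c for c in cols if c in retained]


# ---------------------------------------------------------------------------
# cohort-level featurization


class FeaturePipeline:
    """Turn (pregnancies, censored events, timepoint) into a feature matrix.

    The matrix is a pure function of its inputs: static pregnancy fields,
    per-code series statistics, trend coefficients on times centered at the
    censor point, and censor-schedule bin statistics for blood pressure.
    """

    def __init__(
        self,
        visit_weeks=(14, 20, 24, 28, 32, 34, 36, 38),
        vital_codes=_VITAL_CODES,
        lab_codes=_LAB_CODES,
        c3_lag: int = 2,
    ) -> None:
        self.visit_weeks = tuple(visit_weeks)
        self.vital_codes = tuple(vital_codes)
        self.lab_codes = tuple(lab_codes)
        self.c3_lag = c3_lag

    # -- specs ------------------------------------------------------------
    def specs(self, timepoint_weeks: float) -> list[FeatureSpec]:
        out = []
        for col, cat in _STATIC_CATEGORY.items():
            out.append(FeatureSpec(name=col, source_code="static", transform="static",
                                   category=cat))
        for col in ("race_Black", "race_Asian", "race_Other", "hispanic", "public_insurance"):
            out.append(FeatureSpec(name=col, source_code="static", transform="static",
                                   category="demographics"))
        edges = censor_bin_edges(self.visit_weeks, timepoint_weeks)
        for code in self.vital_codes + self.lab_codes:
            cat = "vital_signs" if code in self.vital_codes else "laboratory"
            for tr in ("mean", "max", "min", "median", "count", "c3_lag2",
                       "trend_linear", "trend_quadratic"):
                out.append(FeatureSpec(name=f"{code}_{tr}", source_code=code,
                                       transform=tr, category=cat))
            if code in self.vital_codes:
                for i in range(len(edges) - 1):
                    for st in ("min", "max", "mean"):
                        out.append(FeatureSpec(name=f"{code}_bin{i + 1}_{st}",
                                               source_code=code, transform="bin_stat",
                                               category=cat, bin_edges=edges))
                for i in range(1, len(edges) - 1):
                    out.append(FeatureSpec(name=f"{code}_delta_mean_bin{i}to{i + 1}",
                                           source_code=code, transform="bin_delta",
                                           category=cat, bin_edges=edges))
        return out

    def provenance(self, timepoint_weeks: float) -> dict[str, FeatureSpec]:
        return {s.name: s for s in self.specs(timepoint_weeks)}

    # -- transform ---------------------------------------------------------
    def _static(self, pregnancies: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=pregnancies["pregnancy_id"])
        for col in _STATIC_CATEGORY:
            out[col] = pregnancies[col].to_numpy(dtype=float)
        race = pregnancies["self_reported_race"]
        for grp in ("Black", "Asian", "Other"):
            out[f"race_{grp}"] = (race == grp).to_numpy(dtype=float)
        out["hispanic"] = (pregnancies["ethnicity"] == "Hispanic").to_numpy(dtype=float)
        out["public_insurance"] = (pregnancies["insurance"] == "Public").to_numpy(dtype=float)
        return out

    def _series_features(self, sub: pd.DataFrame, code: str, censor_days: float,
                         edges) -> pd.DataFrame:
        lag = self.c3_lag
        want_bins = code in self.vital_codes

        def per_group(g: pd.DataFrame) -> pd.Series:
            v = g["value"].to_numpy(dtype=float)
            t_days = g["ga_minutes"].to_numpy(dtype=float) / _MINUTES_PER_DAY
            rec = {f"{code}_{k}": val for k, val in series_summary(v).items()}
            rec[f"{code}_c3_lag2"] = c3_statistic(v, lag)
            b1, b2 = polynomial_trend(t_days - censor_days, v)
            rec[f"{code}_trend_linear"] = b1
            rec[f"{code}_trend_quadratic"] = b2
            if want_bins:
                for key, val in bin_statistics(t_days, v, edges).items():
                    rec[f"{code}_{key}"] = val
            return pd.Series(rec)

        if len(sub) == 0:
            return pd.DataFrame()
        return sub.groupby("pregnancy_id", sort=False).apply(per_group, include_groups=False)

    def transform(self, pregnancies: pd.DataFrame, events: pd.DataFrame,
                  timepoint_weeks: float) -> pd.DataFrame:
        """Featurize already-censored events for the given timepoint."""
        censor_days = timepoint_weeks * 7.0
        edges = censor_bin_edges(self.visit_weeks, timepoint_weeks)
        matrix = self._static(pregnancies)
        obs = events[events["kind"].isin(("vital", "lab"))]
        obs = obs.sort_values(["pregnancy_id", "ga_minutes", "code"], kind="mergesort")
        for code in self.vital_codes + self.lab_codes:
            sub = obs[obs["code"] == code]
            feats = self._series_features(sub, code, censor_days, edges)
            if len(feats):
                matrix = matrix.join(feats, how="left")
            else:
                matrix[f"{code}_count"] = 0.0
        # a pregnancy with no readings of a code has count 0, not missing
        for code in self.vital_codes + self.lab_codes:
            col = f"{code}_count"
            if col in matrix.columns:
                matrix[col] = matrix[col].fillna(0.0)
        expected = [s.name for s in self.specs(timepoint_weeks)]
        for name in expected:
            if name not in matrix.columns:
                matrix[name] = np.nan
        return matrix[expected]


class FeatureSelector:
    """Train/apply-separated missingness + relevance + imputation + VIF stack.

    ``fit`` learns everything from the development matrix; ``transform``
    replays the learned decisions on any matrix with the same columns.
    ``for_linear=True`` additionally restricts to the VIF-pruned subset,
    which the linear model families require.
    """

    def __init__(self, missingness_threshold: float = 0.95, alpha: float = 0.05,
                 vif_threshold: float = 10.0, use_relevance: bool = True) -> None:
        self.missingness_threshold = missingness_threshold
        self.alpha = alpha
        self.vif_threshold = vif_threshold
        self.use_relevance = use_relevance
        self.medians_: pd.Series | None = None
        self.columns_: list[str] | None = None
        self.vif_columns_: list[str] | None = None
        self.relevance_: RelevanceResult | None = None

    def fit(self, matrix: pd.DataFrame, labels) -> "FeatureSelector":
        train, _, medians = impute_and_filter(
            matrix, None, missingness_threshold=self.missingness_threshold
        )
        cols = list(train.columns)
        if self.use_relevance:
            self.relevance_ = relevance_filter(train, labels, alpha=self.alpha)
            kept = set(self.relevance_.retained)
            cols = [c for c in cols if c in kept]
            if not cols:  # degenerate tiny inputs: fall back to all imputable
                cols = list(train.columns)
        self.columns_ = cols
        self.medians_ = medians[cols]
        self.vif_columns_ = vif_prune(train[cols], threshold=self.vif_threshold)
        return self

    def transform(self, matrix: pd.DataFrame, for_linear: bool = False) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("selector is not fitted")
        cols = self.vif_columns_ if for_linear else self.columns_
        return matrix[cols].fillna(self.medians_[cols])
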