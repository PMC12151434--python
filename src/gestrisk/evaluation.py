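"""Discrimination, calibration-by-cutoff, guideline comparison and fairness.

AUC is computed as pairwise concordance — the probability that a randomly
chosen case outscores a randomly chosen control, ties counting one half —
with a stratified percentile-bootstrap 95% confidence interval (cases and
controls resampled separately, 1,000 replicates by default).

The guideline comparator follows the aspirin-prophylaxis risk rule: a
pregnancy is flagged when at least one high-risk factor (prior
preeclampsia, multiple gestation, chronic hypertension, diabetes, kidney
disease, autoimmune disease) or at least two moderate-risk factors
(nulliparity, BMI > 30, family history of preeclampsia, age >= 35,
sociodemographic risk, personal-history factors) are present.

Fairness is audited with the Equality of Opportunity Difference: the gap in
true-positive rates between demographic groups at a fixed decision cutoff,
with a two-sided resampling p-value under the pooled-TPR null (group
memberships permuted among cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "concordance_auc",
    "auc_ci",
    "cutoff_metrics",
    "AcogRiskFactors",
    "acog_factors_from_pregnancies",
    "acog_flag",
    "acog_logistic_comparator",
    "comparator_venn",
    "equality_of_opportunity",
    "cohort_summary",
]

HIGH_RISK_FACTORS = ("prior_preeclampsia", "multiple_gestation", "chronic_htn",
                     "diabetes", "kidney_disease", "autoimmune_disease")
MODERATE_RISK_FACTORS = ("nulliparous", "bmi_over_30", "family_hx_preeclampsia",
                         "age_35_or_over", "sociodemographic_risk",
                         "personal_history_factors")


def concordance_auc(labels, scores) -> float:
    """AUC by pairwise concordance; ties between a case and a control = 0.5."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(s)  # average ranks implement the tie = 0.5 rule
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_ci(labels, scores, n_boot: int = 1000, seed: int = 0) -> tuple[float, float, float]:
    """(auc, lo, hi): stratified percentile bootstrap over cases and controls."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    point = concordance_auc(y, s)
    rng = np.random.default_rng(seed)
    cases, controls = s[y], s[~y]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(cases, size=len(cases), replace=True)
        ct = rng.choice(controls, size=len(controls), replace=True)
        ranks = stats.rankdata(np.concatenate([cs, ct]))
        vals[b] = (ranks[: len(cs)].sum() - len(cs) * (len(cs) + 1) / 2) / (len(cs) * len(ct))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, float(lo), float(hi)


def cutoff_metrics(labels, scores, cutoffs=None) -> pd.DataFrame:
    """Sensitivity, specificity and flagged fraction per probability cutoff.

    A row is flagged when its score strictly exceeds the cutoff, so
    sensitivity is non-increasing and specificity non-decreasing in the
    cutoff for any score vector.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.1, 1.0, 0.1), 10)
    rows = []
    for c in cutoffs:
        flag = s > c
        tp = int((flag & y).sum())
        tn = int((~flag & ~y).sum())
        rows.append(
            {
                "cutoff": float(c),
                "sensitivity": tp / max(int(y.sum()), 1),
                "specificity": tn / max(int((~y).sum()), 1),
                "flagged_fraction": float(flag.mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# guideline comparator


@dataclass(frozen=True)
class AcogRiskFactors:
    prior_preeclampsia: bool = False
    multiple_gestation: bool = False
    chronic_htn: bool = False
    diabetes: bool = False
    kidney_disease: bool = False
    autoimmune_disease: bool = False
    nulliparous: bool = False
    bmi_over_30: bool = False
    family_hx_preeclampsia: bool = False
    age_35_or_over: bool = False
    sociodemographic_risk: bool = False
    personal_history_factors: bool = False


def acog_factors_from_pregnancies(pregnancies: pd.DataFrame) -> pd.DataFrame:
    """Boolean factor table (one row per pregnancy) from static fields."""
    out = pd.DataFrame(index=pregnancies["pregnancy_id"])
    for col in HIGH_RISK_FACTORS:
        out[col] = pregnancies[col].to_numpy(dtype=bool)
    out["nulliparous"] = pregnancies["nulliparous"].to_numpy(dtype=bool)
    out["bmi_over_30"] = (pregnancies["bmi_baseline"] > 30).to_numpy()
    out["family_hx_preeclampsia"] = pregnancies["family_hx_preeclampsia"].to_numpy(dtype=bool)
    out["age_35_or_over"] = (pregnancies["age_years"] >= 35).to_numpy()
    out["sociodemographic_risk"] = pregnancies["sociodemographic_risk"].to_numpy(dtype=bool)
    out["personal_history_factors"] = pregnancies["personal_history_factors"].to_numpy(dtype=bool)
    return out


def acog_flag(factors) -> bool | np.ndarray:
    """>=1 high-risk factor or >=2 moderate-risk factors.

    Accepts a single ``AcogRiskFactors`` (returns bool) or a boolean
    DataFrame from :func:`acog_factors_from_pregnancies` (returns a vector).
    """
    if isinstance(factors, AcogRiskFactors):
        high = any(getattr(factors, f) for f in HIGH_RISK_FACTORS)
        moderate = sum(bool(getattr(factors, f)) for f in MODERATE_RISK_FACTORS)
        return bool(high or moderate >= 2)
    high = factors[list(HIGH_RISK_FACTORS)].to_numpy(dtype=bool).any(axis=1)
    moderate = factors[list(MODERATE_RISK_FACTORS)].to_numpy(dtype=bool).sum(axis=1)
    return high | (moderate >= 2)


def acog_logistic_comparator(factor_matrix: pd.DataFrame, labels, seed: int = 0):
    """Logistic model on the guideline factor columns only (ROC comparator)."""
    from .modeling import fit

    X = factor_matrix.astype(float)
    return fit("logistic", {}, X, labels, seed=seed, resampler="random_over")


def comparator_venn(labels, model_flags, acog_flags) -> dict:
    """Counts comparing model flags, guideline flags and actual cases."""
    y = np.asarray(labels, dtype=bool)
    m = np.asarray(model_flags, dtype=bool)
    a = np.asarray(acog_flags, dtype=bool)
    if not (len(y) == len(m) == len(a)):
        raise ValueError("label and flag vectors must share a length")
    n = len(y)
    return {
        "n": n,
        "cases_total": int(y.sum()),
        "model_flagged": int(m.sum()),
        "acog_flagged": int(a.sum()),
        "overlap": int((m & a).sum()),
        "model_tp": int((m & y).sum()),
        "acog_tp": int((a & y).sum()),
        "model_flagged_fraction": float(m.mean()) if n else 0.0,
        "acog_flagged_fraction": float(a.mean()) if n else 0.0,
    }


# ---------------------------------------------------------------------------
# fairness


def equality_of_opportunity(labels, flags, groups, n_boot: int = 1000,
                            seed: int = 0) -> dict:
    """Per group-pair EOD (TPR difference) with resampling p-values.

    The null permutes group memberships among cases (pooled-TPR null); the
    p-value is the add-one-corrected two-sided tail of |EOD|.  Pairs where
    either group has no cases are omitted.
    """
    y = np.asarray(labels, dtype=bool)
    f = np.asarray(flags, dtype=bool)
    g = np.asarray(groups)
    rng = np.random.default_rng(seed)

    case_flags = f[y]
    case_groups = g[y]
    names = sorted(pd.unique(g).tolist())
    out: dict = {}
    for a, b in combinations(names, 2):
        in_a, in_b = case_groups == a, case_groups == b
        na, nb = int(in_a.sum()), int(in_b.sum())
        if na == 0 or nb == 0:
            continue
        tpr_a = float(case_flags[in_a].mean())
        tpr_b = float(case_flags[in_b].mean())
        eod = tpr_a - tpr_b
        pool = case_flags[in_a | in_b]
        k = len(pool)
        # vectorized membership permutations: first na of each shuffle -> group a
        perm = np.argsort(rng.random((n_boot, k)), axis=1)
        shuffled = pool[perm]
        null = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
        p = (1 + int((np.abs(null) >= abs(eod) - 1e-12).sum())) / (1 + n_boot)
        out[(a, b)] = {"eod": eod, "p_value": float(p),
                       "tpr": {a: tpr_a, b: tpr_b}, "n_cases": {a: na, b: nb}}
    if not out:
        raise ValueError("need at least two groups with cases")
    return out


# ---------------------------------------------------------------------------
# cohort description


def cohort_summary(pregnancies: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-variable summaries by eventual case status with significance tests.

    Continuous variables: mean +/- SD and Student's t-test; boolean or
    categorical variables: n (%) and chi-squared.  ``labels`` must carry
    (pregnancy_id, is_case).
    """
    merged = pregnancies.merge(labels[["pregnancy_id", "is_case"]], on="pregnancy_id")
    case = merged["is_case"].astype(bool)
    rows = []
    skip = {"pregnancy_id", "patient_id", "is_case"}
    for col in merged.columns:
        if col in skip:
            continue
        series = merged[col]
        if series.dtype == bool or series.dtype == object:
            levels = [True] if series.dtype == bool else sorted(series.unique())
            for level in levels:
                ind = series == level
                tab = pd.crosstab(ind, case)
                if tab.shape == (2, 2):
                    p = float(stats.chi2_contingency(tab)[1])
                else:
                    p = float("nan")
                n_case, n_ctrl = int((ind & case).sum()), int((ind & ~case).sum())
                rows.append({
                    "variable": col if series.dtype == bool else f"{col}={level}",
                    "cases": f"{n_case} ({100 * n_case / max(case.sum(), 1):.1f}%)",
                    "controls": f"{n_ctrl} ({100 * n_ctrl / max((~case).sum(), 1):.1f}%)",
                    "overall": f"{int(ind.sum())} ({100 * ind.mean():.1f}%)",
                    "p_value": p,
                    "test": "chi2",
                })
        else:
            a, b = series[case].astype(float), series[~case].astype(float)
            if a.nunique() <= 1 and b.nunique() <= 1 and a.mean() == b.mean():
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            rows.append({
                "variable": col,
                "cases": f"{a.mean():.2f} ± {a.std():.2f}",
                "controls": f"{b.mean():.2f} ± {b.std():.2f}",
                "overall": f"{series.mean():.2f} ± {series.std():.2f}",
                "p_value": p,
                "test": "t",
            })
    return pd.DataFrame(rows)
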