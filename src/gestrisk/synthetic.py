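"""Synthetic longitudinal obstetric EHR cohorts with planted risk structure.

Every downstream stage (phenotyping, censoring, modeling, fairness auditing)
is exercised against cohorts produced here, so the generator plants a *known*
logistic risk surface and records it in a truth sidecar that the pipeline
stages themselves never read.

The generated world:

* one row per pregnancy with demographics, obstetric history and comorbidity
  flags whose marginal rates are calibrated against published summary counts
  of a large US delivery cohort (``REFERENCE_COHORT``);
* prenatal visits at gestational weeks 14, 20, 24, 28, 32, 34, 36 and 38
  (jittered by 0-4 days), each contributing paired systolic/diastolic blood
  pressure readings and a rotating panel of laboratory results;
* cases receive an onset time after 22 weeks; their vitals drift gently
  upward from 20 weeks and escalate sharply at onset so that the rule-based
  phenotype fires, through one of four clinical presentations (hypertension
  with proteinuria, severe-range BP cluster, hypertensive crisis with
  abnormal liver enzymes, or ICD-documented HELLP/eclampsia);
* ICD diagnosis codes are assigned with imperfect sensitivity and
  specificity, so labeling by billing codes alone has a positive predictive
  value well below 1.

Gestational time is tracked in integer minutes from conception (the
phenotyping windows are hour-scale); delivery and onset are stored in days.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "REFERENCE_COHORT",
    "DEFAULT_RISK_COEFFICIENTS",
    "DEFAULT_COVARIATE_MODEL",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_external_cohort",
    "planted_risk",
    "oracle_auc",
    "write_cohort",
    "read_cohort",
]

#: Published summary counts of the development cohort (a 2015-2023 New England
#: delivery population) and of the nulliparous multi-site cohort used for
#: external validation.  These counts calibrate the generator defaults; the
#: pipeline never consumes them directly.
REFERENCE_COHORT = {
    "total": 101_357,
    "cases": 6_160,
    "proteinuria_cases": 3_747,
    "nulliparous_cases": 4_233,
    "external_total": 8_545,
    "external_cases": 536,
}

#: Planted log-odds weights.  Magnitudes follow the direction and rough size
#: of established preeclampsia risk factors (e.g., chronic hypertension
#: roughly quadruples the odds); continuous weights are per unit (years,
#: kg/m^2).
DEFAULT_RISK_COEFFICIENTS: dict[str, float] = {
    "chronic_htn": math.log(4.0),
    "prior_preeclampsia": 1.25,
    "prior_gest_htn": 0.60,
    "multiple_gestation": 0.92,
    "diabetes": 0.41,
    "kidney_disease": 1.10,
    "autoimmune_disease": 0.60,
    "nulliparous": 0.50,
    "ivf": 0.40,
    "family_hx_htn": 0.35,
    "bmi_baseline": 0.045,
    "age_years": 0.010,
}

#: Marginal covariate distribution: rates for booleans, (mean, sd) for
#: numerics.  ``prior_*`` rates are conditional on parity > 0.
DEFAULT_COVARIATE_MODEL: dict[str, float | tuple[float, float]] = {
    "age_years": (33.2, 4.8),
    "bmi_baseline": (29.0, 5.5),
    "nulliparous": 0.577,
    "ivf": 0.043,
    "multiple_gestation": 0.033,
    "chronic_htn": 0.071,
    "diabetes": 0.145,
    "kidney_disease": 0.015,
    "autoimmune_disease": 0.020,
    "family_hx_htn": 0.383,
    "family_hx_preeclampsia": 0.022,
    "prior_preeclampsia": 0.061,
    "prior_gest_htn": 0.090,
    "hispanic": 0.148,
    "public_insurance": 0.30,
    "sociodemographic_risk": 0.15,
    "personal_history_factors": 0.10,
}

_EVENT_COLUMNS = ["pregnancy_id", "ga_minutes", "kind", "code", "value", "units"]

#: ICD families used by the phenotype (kept in sync with phenotyping defaults).
_HELLP_CODES = ("642.7", "O14.1")
_ECLAMPSIA_CODES = ("642.6", "O15")
#: Family-level preeclampsia codes planted by the sensitivity/specificity
#: mechanism.  O14.9 is in the O14 family but is not the HELLP child code.
_PE_FAMILY_CODES = ("642.4", "O11", "O14.9")

_MINUTES_PER_DAY = 1440


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world.

    ``target_incidence`` is the marginal case fraction the planted logistic
    model is calibrated to (default 6.1%, matching the reference cohort).
    ``visit_weeks`` are the prenatal-visit anchors, which double as the
    censoring schedule downstream.
    """

    n_pregnancies: int = 5_000
    target_incidence: float = 0.061
    risk_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_COEFFICIENTS)
    )
    visit_weeks: tuple[int, ...] = (14, 20, 24, 28, 32, 34, 36, 38)
    noise_sd_sbp: float = 6.0
    noise_sd_dbp: float = 4.0
    icd_sensitivity: float = 0.90
    icd_specificity: float = 0.974
    group_mix: dict[str, float] = field(
        default_factory=lambda: {"White": 0.66, "Black": 0.10, "Asian": 0.11, "Other": 0.13}
    )
    #: optional per-group log-odds offsets; empty = group-symmetric risk, the
    #: default under which the fairness null calibration is valid.
    group_risk_shift: dict[str, float] = field(default_factory=dict)
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: {
            "AST": 0.30,
            "ALT": 0.30,
            "URIC_ACID": 0.40,
            "RBC": 0.30,
            "URINE_PROT": 0.40,
        }
    )
    covariate_model: dict[str, float | tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL)
    )
    coefficient_scale: float = 1.0
    nulliparous_only: bool = False
    multi_pregnancy_rate: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pregnancies <= 0:
            raise ConfigError("n_pregnancies must be positive")
        if not 0.0 < self.target_incidence < 1.0:
            raise ConfigError("target_incidence must lie in (0, 1)")
        if abs(sum(self.group_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("group_mix proportions must sum to 1")
        if any(p < 0 for p in self.group_mix.values()):
            raise ConfigError("group_mix proportions must be non-negative")
        weeks = list(self.visit_weeks)
        if weeks != sorted(weeks) or len(set(weeks)) != len(weeks):
            raise ConfigError("visit_weeks must be strictly increasing")
        for name, val in (("icd_sensitivity", self.icd_sensitivity),
                          ("icd_specificity", self.icd_specificity)):
            if not 0.0 < val <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort: pregnancies, long-format events, truth sidecar."""

    pregnancies: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        ids = set(self.pregnancies["pregnancy_id"])
        truth_ids = set(self.truth["pregnancy_id"])
        if ids != truth_ids or len(self.truth) != len(ids):
            raise ValueError("truth sidecar must cover every pregnancy exactly once")


def planted_risk(pregnancy, coefficients: dict[str, float], intercept: float = 0.0) -> float:
    """Inverse-logit of ``intercept + sum(coefficient * feature)``.

    ``pregnancy`` is any mapping (dict, pandas Series, dataclass-as-dict)
    exposing the coefficient-named features; booleans count as 0/1.
    """
    lp = float(intercept)
    for name, coef in coefficients.items():
        if name == "intercept":
            lp += coef
            continue
        try:
            value = pregnancy[name]
        except (KeyError, IndexError, TypeError) as exc:
            raise KeyError(f"unknown feature in risk coefficients: {name!r}") from exc
        lp += coef * float(value)
    return float(expit(lp))


def oracle_auc(cohort: SyntheticCohort) -> float:
    """Pairwise-concordance AUC of the planted risk against true case status.

    This is the Bayes-optimal discrimination achievable from the planted
    covariates and therefore an upper bound (up to sampling noise) for any
    model trained on them.
    """
    from .evaluation import concordance_auc  # local import avoids a cycle

    y = cohort.truth["true_case"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("AUC undefined: truth contains a single class")
    return concordance_auc(y, cohort.truth["true_risk"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# generation internals


def _covariate(model: dict, name: str):
    try:
        return model[name]
    except KeyError as exc:
        raise ConfigError(f"covariate model missing entry {name!r}") from exc


def _draw_pregnancies(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_pregnancies
    cov = cfg.covariate_model

    # patient assignment: a fraction of patients contribute two pregnancies
    patient_ids = np.empty(n, dtype=object)
    pid = 0
    i = 0
    pair = rng.random(n) < cfg.multi_pregnancy_rate
    while i < n:
        patient_ids[i] = f"PT{pid:06d}"
        if pair[i] and i + 1 < n:
            patient_ids[i + 1] = f"PT{pid:06d}"
            i += 2
        else:
            i += 1
        pid += 1

    age_mu, age_sd = _covariate(cov, "age_years")
    bmi_mu, bmi_sd = _covariate(cov, "bmi_baseline")
    age = np.clip(rng.normal(age_mu, age_sd, n), 16.0, 52.0)
    bmi = np.clip(rng.normal(bmi_mu, bmi_sd, n), 16.0, 55.0)

    p_nullip = 1.0 if cfg.nulliparous_only else float(np.clip(_covariate(cov, "nulliparous"), 0, 1))
    nulliparous = rng.random(n) < p_nullip
    parity = np.where(nulliparous, 0, 1 + rng.poisson(0.55, n))
    gravidity = parity + 1 + rng.poisson(0.30, n)  # counts the index pregnancy

    def bern(name: str) -> np.ndarray:
        return rng.random(n) < float(np.clip(_covariate(cov, name), 0, 1))

    groups = list(cfg.group_mix)
    race = rng.choice(groups, size=n, p=np.asarray([cfg.group_mix[g] for g in groups]))

    frame = pd.DataFrame(
        {
            "pregnancy_id": [f"PG{i:06d}" for i in range(n)],
            "patient_id": patient_ids,
            "age_years": age,
            "self_reported_race": race,
            "ethnicity": np.where(bern("hispanic"), "Hispanic", "Non-Hispanic"),
            "insurance": np.where(bern("public_insurance"), "Public", "Private"),
            "gravidity": gravidity,
            "parity": parity,
            "nulliparous": nulliparous,
            "ivf": bern("ivf"),
            "multiple_gestation": bern("multiple_gestation"),
            "chronic_htn": bern("chronic_htn"),
            "prior_preeclampsia": ~nulliparous & bern("prior_preeclampsia"),
            "prior_gest_htn": ~nulliparous & bern("prior_gest_htn"),
            "diabetes": bern("diabetes"),
            "kidney_disease": bern("kidney_disease"),
            "autoimmune_disease": bern("autoimmune_disease"),
            "family_hx_htn": bern("family_hx_htn"),
            "family_hx_preeclampsia": bern("family_hx_preeclampsia"),
            "sociodemographic_risk": bern("sociodemographic_risk"),
            "personal_history_factors": bern("personal_history_factors"),
            "bmi_baseline": bmi,
        }
    )
    return frame


def _linear_predictor(frame: pd.DataFrame, cfg: GeneratorConfig) -> np.ndarray:
    lp = np.zeros(len(frame))
    for name, coef in cfg.risk_coefficients.items():
        if name == "intercept":
            lp += coef
            continue
        if name not in frame.columns:
            raise ConfigError(f"risk coefficient references unknown feature {name!r}")
        lp += coef * frame[name].to_numpy(dtype=float)
    lp *= cfg.coefficient_scale
    if cfg.group_risk_shift:
        shift = frame["self_reported_race"].map(cfg.group_risk_shift).fillna(0.0)
        lp += shift.to_numpy(dtype=float)
    return lp


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    lo, hi = -25.0, 10.0

    def gap(c: float) -> float:
        return float(np.mean(expit(c + lp))) - target

    if np.allclose(lp, lp[0]):
        return float(logit(target)) - float(lp[0])
    return float(brentq(gap, lo, hi, xtol=1e-12))


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a full cohort.  Deterministic for a fixed config (seed included)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    preg = _draw_pregnancies(cfg, rng)
    n = len(preg)

    lp = _linear_predictor(preg, cfg)
    intercept = _calibrate_intercept(lp, cfg.target_incidence)
    true_risk = expit(intercept + lp)
    true_case = rng.random(n) < true_risk

    # onset after 22 weeks, skewed toward the third trimester
    onset = np.where(true_case, 154.0 + rng.beta(2.0, 1.5, n) * 126.0, np.nan)
    delivery = np.where(
        true_case,
        np.minimum(onset + rng.uniform(3.0, 21.0, n), 294.0),
        np.clip(rng.normal(273.0, 12.0, n), 196.0, 294.0),
    )
    preg["delivery_ga_days"] = np.round(delivery).astype(int)
    onset_days = np.where(true_case, np.round(onset), np.nan)

    # per-person hemodynamic baselines; comorbidity raises resting pressure
    sbp0 = rng.normal(112.0, 8.0, n) + 10.0 * preg["chronic_htn"].to_numpy() \
        + 0.30 * (preg["bmi_baseline"].to_numpy() - 29.0)
    dbp0 = rng.normal(70.0, 6.0, n) + 5.0 * preg["chronic_htn"].to_numpy()
    drift_sbp = np.where(true_case, rng.uniform(0.10, 0.25, n), 0.0)  # mmHg/day from wk 20

    presentation = np.where(
        true_case,
        rng.choice(
            ["proteinuric", "severe", "crisis_lft", "icd_only"],
            size=n,
            p=[0.61, 0.20, 0.10, 0.09],
        ),
        "",
    )

    # controls: a few percent develop gestational hypertension (moderate BP,
    # no proteinuria, never severe) and a small fraction have proteinuria
    gest_htn = ~true_case & (rng.random(n) < 0.04)
    control_prot = ~true_case & (rng.random(n) < 0.006)

    icd_case_draw = rng.random(n) < cfg.icd_sensitivity
    icd_fp_draw = rng.random(n) < (1.0 - cfg.icd_specificity)

    lab_weeks = {cfg.visit_weeks[i] for i in range(0, len(cfg.visit_weeks), 3)} \
        if cfg.visit_weeks else set()

    rows: list[tuple] = []
    miss = cfg.missingness_rates

    def emit(pid, minutes, kind, code, value, units):
        rows.append((pid, int(minutes), kind, code, value, units))

    def emit_lab(pid, minutes, code, value, units):
        if rng.random() >= miss.get(code, 0.0):
            emit(pid, minutes, "lab", code, value, units)

    delivery_days = preg["delivery_ga_days"].to_numpy()
    for i in range(n):
        pid = preg.at[i, "pregnancy_id"]
        dlv_min = delivery_days[i] * _MINUTES_PER_DAY
        case = bool(true_case[i])
        onset_i = onset_days[i] if case else np.nan

        visit_days = []
        for wk in cfg.visit_weeks:
            day = wk * 7 + int(rng.integers(0, 5))
            if day < delivery_days[i]:
                visit_days.append((wk, day))

        for wk, day in visit_days:
            base_minutes = day * _MINUTES_PER_DAY + 8 * 60
            elev_s = elev_d = 0.0
            if case and day > 140:
                elev_s = drift_sbp[i] * (day - 140)
                elev_d = 0.5 * elev_s
            if case and not np.isnan(onset_i) and day >= onset_i:
                elev_s += 40.0
                elev_d += 22.0
            if gest_htn[i] and day >= 210:
                elev_s += 20.0
                elev_d += 10.0

            n_bp = int(rng.integers(1, 4))
            offsets = np.sort(rng.choice(np.arange(0, 180, 5), size=n_bp, replace=False))
            for off in offsets:
                t = base_minutes + int(off)
                if t >= dlv_min:
                    continue
                sbp = sbp0[i] + elev_s + rng.normal(0.0, cfg.noise_sd_sbp)
                dbp = dbp0[i] + elev_d + rng.normal(0.0, cfg.noise_sd_dbp)
                emit(pid, t, "vital", "SBP", round(float(sbp), 1), "mmHg")
                emit(pid, t, "vital", "DBP", round(float(dbp), 1), "mmHg")

            t_lab = base_minutes + 200
            if t_lab < dlv_min:
                if rng.random() < 0.6:
                    if control_prot[i]:
                        up = rng.uniform(0.30, 0.80)
                    elif case and presentation[i] == "proteinuric" and day >= (onset_i or 1e9):
                        up = max(rng.normal(0.6, 0.2), 0.35)
                    else:
                        up = rng.uniform(0.02, 0.20)
                    emit_lab(pid, t_lab, "URINE_PROT", round(float(up), 3), "mg/mg")
                if wk in lab_weeks:
                    ast = np.clip(rng.normal(22.0, 6.0), 5.0, 60.0)
                    alt = np.clip(rng.normal(20.0, 7.0), 5.0, 60.0)
                    uric = rng.normal(4.3, 0.8)
                    rbc = rng.normal(4.1, 0.35)
                    if case and day > 140:
                        uric += 0.004 * (day - 140)
                        rbc += rng.normal(0.0, 0.15)
                    emit_lab(pid, t_lab, "AST", round(float(ast), 1), "U/L")
                    emit_lab(pid, t_lab, "ALT", round(float(alt), 1), "U/L")
                    emit_lab(pid, t_lab, "URIC_ACID", round(float(uric), 2), "mg/dL")
                    emit_lab(pid, t_lab, "RBC", round(float(rbc), 2), "x10^6/uL")

        if case:
            t0 = int(onset_i) * _MINUTES_PER_DAY + 8 * 60
            kind = presentation[i]
            if kind == "proteinuric":
                for t in (t0, t0 + 4 * 60 + int(rng.integers(0, 120))):
                    sbp = max(rng.normal(155.0, 5.0), 145.0)
                    dbp = max(rng.normal(97.0, 4.0), 92.0)
                    emit(pid, t, "vital", "SBP", round(float(sbp), 1), "mmHg")
                    emit(pid, t, "vital", "DBP", round(float(dbp), 1), "mmHg")
                up = max(rng.normal(0.6, 0.2), 0.35)
                emit(pid, t0 + int(rng.integers(10, 70)), "lab", "URINE_PROT",
                     round(float(up), 3), "mg/mg")
            elif kind == "severe":
                t = t0
                for _ in range(7):
                    sbp = max(rng.normal(172.0, 5.0), 163.0)
                    dbp = max(rng.normal(108.0, 4.0), 102.0)
                    emit(pid, t, "vital", "SBP", round(float(sbp), 1), "mmHg")
                    emit(pid, t, "vital", "DBP", round(float(dbp), 1), "mmHg")
                    t += int(rng.integers(8, 16))
            elif kind == "crisis_lft":
                sbp = max(rng.normal(182.0, 6.0), 172.0)
                dbp = max(rng.normal(114.0, 5.0), 111.0)
                emit(pid, t0, "vital", "SBP", round(float(sbp), 1), "mmHg")
                emit(pid, t0, "vital", "DBP", round(float(dbp), 1), "mmHg")
                emit(pid, t0 + 30, "lab", "AST",
                     round(float(max(rng.normal(95.0, 20.0), 70.0)), 1), "U/L")
                emit(pid, t0 + 30, "lab", "ALT",
                     round(float(max(rng.normal(100.0, 20.0), 75.0)), 1), "U/L")
            else:  # icd_only: HELLP or eclampsia billing code documents the case
                code = _HELLP_CODES[1] if rng.random() < 0.5 else _ECLAMPSIA_CODES[1]
                emit(pid, t0, "icd", code, np.nan, "")

            if icd_case_draw[i]:
                t_icd = min(
                    t0 + int(rng.uniform(0.0, 3.0) * _MINUTES_PER_DAY),
                    dlv_min - 1,
                )
                code = _PE_FAMILY_CODES[int(rng.integers(0, len(_PE_FAMILY_CODES)))]
                emit(pid, t_icd, "icd", code, np.nan, "")
        elif icd_fp_draw[i] and visit_days:
            # suspicion-of-disease coding in a patient who never qualifies
            _, day = visit_days[int(rng.integers(0, len(visit_days)))]
            code = _PE_FAMILY_CODES[int(rng.integers(0, len(_PE_FAMILY_CODES)))]
            emit(pid, day * _MINUTES_PER_DAY + 10 * 60, "icd", code, np.nan, "")

    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    events = events.sort_values(
        ["pregnancy_id", "ga_minutes", "kind", "code"], kind="mergesort"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "pregnancy_id": preg["pregnancy_id"],
            "true_case": true_case,
            "true_risk": true_risk,
            "true_onset_ga_days": onset_days,
        }
    )
    return SyntheticCohort(pregnancies=preg, events=events, truth=truth, config=cfg)


def generate_external_cohort(config: GeneratorConfig, shift: dict | None = None) -> SyntheticCohort:
    """Draw a distribution-shifted cohort standing in for external validation.

    ``shift`` keys (all optional): ``coefficient_scale`` (multiplies every
    planted weight), ``covariate_shift`` (additive deltas on covariate rates
    or on the means of numeric covariates), ``nulliparous_only`` (restrict to
    first pregnancies, as in a nulliparous study design), ``target_incidence``
    and ``seed`` overrides.  An empty shift reproduces ``generate_cohort``.
    """
    shift = dict(shift or {})
    cov = dict(config.covariate_model)
    for name, delta in dict(shift.pop("covariate_shift", {})).items():
        base = cov.get(name)
        if base is None:
            raise ConfigError(f"covariate_shift references unknown covariate {name!r}")
        if isinstance(base, tuple):
            cov[name] = (base[0] + delta, base[1])
        else:
            cov[name] = float(np.clip(base + delta, 0.0, 1.0))
    updates = {"covariate_model": cov}
    for key in ("coefficient_scale", "nulliparous_only", "target_incidence", "seed",
                "n_pregnancies", "group_mix"):
        if key in shift:
            updates[key] = shift.pop(key)
    if "coefficient_scale" in updates:
        updates["coefficient_scale"] = config.coefficient_scale * updates["coefficient_scale"]
    if shift:
        raise ConfigError(f"unknown shift keys: {sorted(shift)}")
    return generate_cohort(replace(config, **updates))


# ---------------------------------------------------------------------------
# on-disk format: long-format events + one-row-per-pregnancy + truth sidecar


def write_cohort(cohort: SyntheticCohort, directory, fmt: str = "csv") -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = {
        "events": cohort.events,
        "pregnancies": cohort.pregnancies,
        "truth": cohort.truth,  # sidecar: consumed only by oracle checks
    }
    for name, frame in frames.items():
        if fmt == "csv":
            frame.to_csv(directory / f"{name}.csv", index=False)
        elif fmt == "parquet":
            frame.to_parquet(directory / f"{name}.parquet", index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_cohort(directory, fmt: str = "csv", with_truth: bool = True) -> SyntheticCohort:
    from pathlib import Path

    directory = Path(directory)
    reader = pd.read_csv if fmt == "csv" else pd.read_parquet
    preg = reader(directory / f"pregnancies.{fmt}")
    events = reader(directory / f"events.{fmt}")
    if with_truth and (directory / f"truth.{fmt}").exists():
        truth = reader(directory / f"truth.{fmt}")
    else:
        truth = pd.DataFrame(
            {
                "pregnancy_id": preg["pregnancy_id"],
                "true_case": False,
                "true_risk": np.nan,
                "true_onset_ga_days": np.nan,
            }
        )
    return SyntheticCohort(pregnancies=preg, events=events, truth=truth)
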