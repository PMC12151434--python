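"""Rule-based preeclampsia phenotype over timestamped clinical events.

Billing codes alone identify preeclampsia poorly (their positive predictive
value is well below 1), so the case label is assigned by a five-criterion
algorithm over blood-pressure readings, laboratory values and ICD codes:

1. two BP readings above the moderate threshold (>140/90 mmHg) at least
   4 hours apart, combined with proteinuria;
2. repeated severe-range BP: at least 7 readings above 160/100 mmHg within a
   2-hour window;
3. a HELLP-syndrome ICD diagnosis (642.7 / O14.1);
4. an eclampsia ICD diagnosis (642.6 / O15);
5. a hypertensive-crisis reading (>170/110 mmHg) supported by either a
   preeclampsia-family ICD code (642.4, 642.5 / O11, O14) or abnormal liver
   function tests (AST > 64 or ALT > 70 U/L).

Because ICD codes are often entered only after the clinical criteria are
met, the diagnosis is dated at the first qualifying blood-pressure (or
proteinuria) observation for the BP-based criteria, and at the code's own
timestamp for the ICD-only criteria.  A criterion only makes a case when it
fires at or after 20 weeks (140 days) of gestation, matching the clinical
definition of new-onset disease.

All thresholds use strict inequality and OR semantics across the systolic /
diastolic components (clinical staging convention); both choices are
configurable.  Systolic and diastolic readings are paired on identical
gestational minutes; a minute with only one component is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeConfig",
    "PhenotypeLabel",
    "bp_readings",
    "find_sustained_htn_with_proteinuria",
    "find_severe_cluster",
    "find_icd",
    "find_crisis_with_support",
    "assign_phenotype",
    "icd_only_label",
    "phenotype_cohort",
]

_MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class PhenotypeConfig:
    bp_moderate: tuple[float, float] = (140.0, 90.0)
    bp_severe: tuple[float, float] = (160.0, 100.0)
    bp_crisis: tuple[float, float] = (170.0, 110.0)
    moderate_gap_hours: float = 4.0
    severe_count: int = 7
    severe_window_hours: float = 2.0
    ast_threshold: float = 64.0
    alt_threshold: float = 70.0
    icd_hellp: frozenset[str] = frozenset({"642.7", "O14.1"})
    icd_eclampsia: frozenset[str] = frozenset({"642.6", "O15"})
    icd_preeclampsia: frozenset[str] = frozenset({"642.4", "642.5", "O11", "O14"})
    min_ga_days: int = 140
    #: "or": either component above threshold qualifies (staging convention)
    bp_semantics: str = "or"
    proteinuria_threshold: float = 0.3
    proteinuria_codes: frozenset[str] = frozenset({"791.0", "R80"})
    require_both_lfts: bool = False

    def __post_init__(self) -> None:
        for lo, hi in ((self.bp_moderate, self.bp_severe), (self.bp_severe, self.bp_crisis)):
            if hi[0] < lo[0] or hi[1] < lo[1]:
                raise ValueError("BP tiers must be componentwise non-decreasing")
        if self.moderate_gap_hours <= 0 or self.severe_window_hours <= 0:
            raise ValueError("gaps and windows must be positive")
        if self.bp_semantics not in ("or", "and"):
            raise ValueError("bp_semantics must be 'or' or 'and'")


@dataclass(frozen=True)
class PhenotypeLabel:
    pregnancy_id: str
    is_case: bool
    criterion_id: int | None = None
    diagnosis_ga_minutes: int | None = None

    def __post_init__(self) -> None:
        present = (self.criterion_id is not None, self.diagnosis_ga_minutes is not None)
        if self.is_case != all(present) or (not self.is_case and any(present)):
            raise ValueError("criterion and diagnosis time must be present iff case")


def _code_matches(code, code_set) -> bool:
    code = str(code)
    return any(code.startswith(str(c)) for c in code_set)


@dataclass
class _View:
    """One pregnancy's events reduced to the arrays the criteria need."""

    pregnancy_id: str
    bp_t: np.ndarray      # paired reading times (minutes), sorted
    sbp: np.ndarray
    dbp: np.ndarray
    prot_t: np.ndarray    # qualifying proteinuria times, sorted
    icd_t: np.ndarray
    icd_codes: np.ndarray
    ast_high: bool
    alt_high: bool

    def exceeds(self, threshold, semantics: str) -> np.ndarray:
        s = self.sbp > threshold[0]
        d = self.dbp > threshold[1]
        return (s | d) if semantics == "or" else (s & d)


def _pair_bp(times_s, vals_s, times_d, vals_d):
    """Pair components on identical minute; duplicates keep first occurrence."""
    common, ia, ib = np.intersect1d(times_s, times_d, return_indices=True)
    return common, vals_s[ia], vals_d[ib]


def _build_view(pid, t, kind, code, value, cfg: PhenotypeConfig) -> _View:
    is_vital = kind == "vital"
    is_lab = kind == "lab"
    is_icd = kind == "icd"
    s_mask = is_vital & (code == "SBP")
    d_mask = is_vital & (code == "DBP")
    bp_t, sbp, dbp = _pair_bp(t[s_mask], value[s_mask], t[d_mask], value[d_mask])

    prot_lab = is_lab & (code == "URINE_PROT") & (value >= cfg.proteinuria_threshold)
    prot_t = t[prot_lab]
    icd_t, icd_codes = t[is_icd], code[is_icd]
    if len(icd_codes):
        dx = np.array([_code_matches(c, cfg.proteinuria_codes) for c in icd_codes])
        prot_t = np.concatenate([prot_t, icd_t[dx]])
    ast = value[is_lab & (code == "AST")]
    alt = value[is_lab & (code == "ALT")]
    return _View(
        pregnancy_id=str(pid),
        bp_t=bp_t,
        sbp=sbp,
        dbp=dbp,
        prot_t=np.sort(prot_t),
        icd_t=icd_t,
        icd_codes=icd_codes,
        ast_high=bool(len(ast)) and bool(np.nanmax(ast) > cfg.ast_threshold),
        alt_high=bool(len(alt)) and bool(np.nanmax(alt) > cfg.alt_threshold),
    )


def _check_sorted(events: pd.DataFrame) -> None:
    t = events["ga_minutes"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError("events must be sorted by ga_minutes")


def _view_from_frame(events: pd.DataFrame, cfg: PhenotypeConfig, check_sorted=True) -> _View:
    if check_sorted:
        _check_sorted(events)
    ids = events["pregnancy_id"].unique() if len(events) else np.array([""])
    if len(ids) > 1:
        raise ValueError("expected events from a single pregnancy")
    return _build_view(
        ids[0],
        events["ga_minutes"].to_numpy(dtype=np.int64),
        events["kind"].to_numpy(dtype=object),
        events["code"].to_numpy(dtype=object),
        events["value"].to_numpy(dtype=float),
        cfg,
    )


# ---------------------------------------------------------------------------
# the five criteria (operating on views)


def _crit_sustained(view: _View, cfg: PhenotypeConfig, min_time: int) -> int | None:
    if len(view.prot_t) == 0:
        return None
    times = view.bp_t[view.exceeds(cfg.bp_moderate, cfg.bp_semantics)]
    if len(times) < 2:
        return None
    gap = cfg.moderate_gap_hours * 60.0
    eligible = times[(times >= min_time) & (times[-1] - times >= gap)]
    return int(eligible[0]) if len(eligible) else None


def _crit_severe(view: _View, cfg: PhenotypeConfig, min_time: int) -> int | None:
    times = view.bp_t[view.exceeds(cfg.bp_severe, cfg.bp_semantics)]
    k = cfg.severe_count
    if len(times) < k:
        return None
    window = cfg.severe_window_hours * 60.0
    start = times[: len(times) - k + 1]
    ok = (start >= min_time) & (times[k - 1:] - start <= window)
    hit = np.flatnonzero(ok)
    return int(start[hit[0]]) if len(hit) else None


def _crit_icd(view: _View, code_set, min_time: int) -> int | None:
    if not code_set:
        raise ValueError("code_set must be nonempty")
    if len(view.icd_codes) == 0:
        return None
    match = np.array([_code_matches(c, code_set) for c in view.icd_codes])
    times = view.icd_t[match & (view.icd_t >= min_time)]
    return int(times.min()) if len(times) else None


def _crit_crisis(view: _View, cfg: PhenotypeConfig, min_time: int) -> int | None:
    times = view.bp_t[view.exceeds(cfg.bp_crisis, cfg.bp_semantics)]
    times = times[times >= min_time]
    if len(times) == 0:
        return None
    lft = (view.ast_high and view.alt_high) if cfg.require_both_lfts \
        else (view.ast_high or view.alt_high)
    has_pe = any(_code_matches(c, cfg.icd_preeclampsia) for c in view.icd_codes)
    return int(times[0]) if (lft or has_pe) else None


def _assign(view: _View, cfg: PhenotypeConfig) -> PhenotypeLabel:
    min_time = cfg.min_ga_days * _MINUTES_PER_DAY
    candidates: list[tuple[int, int, int]] = []  # (qualifying, criterion, diagnosis)

    t1 = _crit_sustained(view, cfg, min_time)
    if t1 is not None:
        prot = view.prot_t[view.prot_t >= min_time]
        diag = int(min([t1, *prot.tolist()]))
        candidates.append((t1, 1, diag))
    t2 = _crit_severe(view, cfg, min_time)
    if t2 is not None:
        candidates.append((t2, 2, t2))
    t3 = _crit_icd(view, cfg.icd_hellp, min_time)
    if t3 is not None:
        candidates.append((t3, 3, t3))
    t4 = _crit_icd(view, cfg.icd_eclampsia, min_time)
    if t4 is not None:
        candidates.append((t4, 4, t4))
    t5 = _crit_crisis(view, cfg, min_time)
    if t5 is not None:
        candidates.append((t5, 5, t5))

    if not candidates:
        return PhenotypeLabel(pregnancy_id=view.pregnancy_id, is_case=False)
    _, criterion, diagnosis = min(candidates)
    return PhenotypeLabel(
        pregnancy_id=view.pregnancy_id, is_case=True,
        criterion_id=criterion, diagnosis_ga_minutes=diagnosis,
    )


# ---------------------------------------------------------------------------
# public per-pregnancy API


def bp_readings(events: pd.DataFrame) -> pd.DataFrame:
    """Pair systolic and diastolic readings issued at the same minute."""
    view = _view_from_frame(events, PhenotypeConfig(), check_sorted=False)
    return pd.DataFrame({"ga_minutes": view.bp_t, "sbp": view.sbp, "dbp": view.dbp})


def find_sustained_htn_with_proteinuria(
    events: pd.DataFrame, cfg: PhenotypeConfig, min_time: int = 0
) -> int | None:
    """Criterion 1: moderate-range pair >= 4 h apart plus proteinuria.

    Returns the earliest time T >= ``min_time`` that starts a qualifying
    pair (T is the first reading of the pair); proteinuria may occur at any
    time during the pregnancy.
    """
    return _crit_sustained(_view_from_frame(events, cfg), cfg, min_time)


def find_severe_cluster(
    events: pd.DataFrame, cfg: PhenotypeConfig, min_time: int = 0
) -> int | None:
    """Criterion 2: >= ``severe_count`` severe-range readings within the window."""
    return _crit_severe(_view_from_frame(events, cfg), cfg, min_time)


def find_icd(events: pd.DataFrame, code_set, min_time: int = 0) -> int | None:
    """Earliest time of any ICD event in ``code_set``.

    Matching is by prefix so that family-level codes cover their children
    (O14 matches O14.1; 642.4 matches 642.41).
    """
    view = _view_from_frame(events, PhenotypeConfig(), check_sorted=False)
    return _crit_icd(view, code_set, min_time)


def find_crisis_with_support(
    events: pd.DataFrame, cfg: PhenotypeConfig, min_time: int = 0
) -> int | None:
    """Criterion 5: crisis-range reading plus (PE-family ICD or abnormal LFTs)."""
    return _crit_crisis(_view_from_frame(events, cfg), cfg, min_time)


def assign_phenotype(events: pd.DataFrame, cfg: PhenotypeConfig | None = None) -> PhenotypeLabel:
    """Apply all five criteria to one pregnancy's complete event stream.

    The winning criterion is the one with the earliest qualifying time at or
    after 20 weeks (ties broken by the lower criterion number); the
    diagnosis is dated at the first qualifying BP-or-proteinuria observation
    for the BP-based criteria and at the code time for the ICD-only ones.
    """
    cfg = cfg or PhenotypeConfig()
    if len(events) and events["pregnancy_id"].nunique() > 1:
        raise ValueError("assign_phenotype expects events from a single pregnancy")
    events = events.sort_values("ga_minutes", kind="mergesort")
    return _assign(_view_from_frame(events, cfg), cfg)


def icd_only_label(events: pd.DataFrame, cfg: PhenotypeConfig | None = None) -> bool:
    """Deliberately imperfect comparator: any listed billing code present."""
    cfg = cfg or PhenotypeConfig()
    codes = cfg.icd_hellp | cfg.icd_eclampsia | cfg.icd_preeclampsia
    icd = events[events["kind"] == "icd"]
    return any(_code_matches(c, codes) for c in icd["code"])


def phenotype_cohort(events: pd.DataFrame, cfg: PhenotypeConfig | None = None) -> pd.DataFrame:
    """Label every pregnancy in a long-format event table.

    Returns one row per pregnancy present in ``events`` with columns
    (pregnancy_id, is_case, criterion_id, diagnosis_ga_minutes, icd_only).
    """
    cfg = cfg or PhenotypeConfig()
    ev = events.sort_values(["pregnancy_id", "ga_minutes"], kind="mergesort")
    pid = ev["pregnancy_id"].to_numpy()
    t = ev["ga_minutes"].to_numpy(dtype=np.int64)
    kind = ev["kind"].to_numpy(dtype=object)
    code = ev["code"].to_numpy(dtype=object)
    value = ev["value"].to_numpy(dtype=float)
    comparator_codes = cfg.icd_hellp | cfg.icd_eclampsia | cfg.icd_preeclampsia

    bounds = np.flatnonzero(np.concatenate([[True], pid[1:] != pid[:-1], [True]]))
    records = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        view = _build_view(pid[a], t[a:b], kind[a:b], code[a:b], value[a:b], cfg)
        label = _assign(view, cfg)
        records.append(
            {
                "pregnancy_id": view.pregnancy_id,
                "is_case": label.is_case,
                "criterion_id": label.criterion_id,
                "diagnosis_ga_minutes": label.diagnosis_ga_minutes,
                "icd_only": any(_code_matches(c, comparator_codes) for c in view.icd_codes),
            }
        )
    return pd.DataFrame.from_records(records)
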