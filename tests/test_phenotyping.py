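"""Five-criterion phenotype: hand-built charts, brute-force oracle, invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gestrisk.phenotyping import (
    PhenotypeConfig,
    assign_phenotype,
    bp_readings,
    find_crisis_with_support,
    find_icd,
    find_severe_cluster,
    find_sustained_htn_with_proteinuria,
    icd_only_label,
)

from conftest import DAY, bp, chart, ev

CFG = PhenotypeConfig()
T0 = 210 * DAY + 8 * 60  # GA day 210, 08:00


def prot(pid, minutes, value=0.5):
    return ev(pid, minutes, "lab", "URINE_PROT", value)


# ---------------------------------------------------------------------------
# criterion 1: moderate pair >= 4 h apart + proteinuria


def test_sustained_pair_with_proteinuria_qualifies_at_first_reading():
    events = chart([*bp("a", T0, 150, 95), *bp("a", T0 + 5 * 60, 150, 95),
                    prot("a", T0 + 30)])
    assert find_sustained_htn_with_proteinuria(events, CFG) == T0


def test_sustained_pair_three_hours_apart_fails_gap():
    events = chart([*bp("a", T0, 150, 95), *bp("a", T0 + 3 * 60, 150, 95),
                    prot("a", T0 + 30)])
    assert find_sustained_htn_with_proteinuria(events, CFG) is None


def test_sustained_pair_exactly_four_hours_qualifies():
    events = chart([*bp("a", T0, 141, 80), *bp("a", T0 + 4 * 60, 150, 95),
                    prot("a", T0)])
    assert find_sustained_htn_with_proteinuria(events, CFG) == T0


def test_sustained_without_proteinuria_fails():
    events = chart([*bp("a", T0, 150, 95), *bp("a", T0 + 5 * 60, 150, 95)])
    assert find_sustained_htn_with_proteinuria(events, CFG) is None


def test_sustained_threshold_is_strict():
    # exactly 140/90 does not exceed the moderate threshold
    events = chart([*bp("a", T0, 140, 90), *bp("a", T0 + 5 * 60, 140, 90),
                    prot("a", T0)])
    assert find_sustained_htn_with_proteinuria(events, CFG) is None


def test_sustained_or_semantics_diastolic_alone():
    events = chart([*bp("a", T0, 120, 95), *bp("a", T0 + 5 * 60, 118, 96),
                    prot("a", T0)])
    assert find_sustained_htn_with_proteinuria(events, CFG) == T0


def test_sustained_and_semantics_requires_both_components():
    cfg = PhenotypeConfig(bp_semantics="and")
    events = chart([*bp("a", T0, 120, 95), *bp("a", T0 + 5 * 60, 118, 96),
                    prot("a", T0)])
    assert find_sustained_htn_with_proteinuria(events, cfg) is None


def test_sustained_proteinuria_below_threshold_does_not_count():
    events = chart([*bp("a", T0, 150, 95), *bp("a", T0 + 5 * 60, 150, 95),
                    prot("a", T0, value=0.1)])
    assert find_sustained_htn_with_proteinuria(events, CFG) is None


def test_sustained_proteinuria_diagnosis_code_counts():
    events = chart([*bp("a", T0, 150, 95), *bp("a", T0 + 5 * 60, 150, 95),
                    ev("a", T0, "icd", "R80.9")])
    assert find_sustained_htn_with_proteinuria(events, CFG) == T0


def test_empty_chart_returns_none():
    events = chart([])
    events["pregnancy_id"] = events["pregnancy_id"].astype(object)
    assert find_sustained_htn_with_proteinuria(events, CFG) is None


# ---------------------------------------------------------------------------
# criterion 2: severe cluster


def test_severe_seven_readings_in_90_minutes_qualifies():
    rows = []
    for k in range(7):
        rows += bp("a", T0 + 15 * k, 165, 105)
    assert find_severe_cluster(chart(rows), CFG) == T0


def test_severe_six_readings_insufficient():
    rows = []
    for k in range(6):
        rows += bp("a", T0 + 15 * k, 165, 105)
    assert find_severe_cluster(chart(rows), CFG) is None


def test_severe_seven_readings_spread_over_150_minutes_fails_window():
    rows = []
    for k in range(7):
        rows += bp("a", T0 + 25 * k, 165, 105)
    assert find_severe_cluster(chart(rows), CFG) is None


def test_severe_window_boundary_exactly_two_hours_counts():
    rows = []
    for k in range(7):
        rows += bp("a", T0 + 20 * k, 165, 105)  # span exactly 120 min
    assert find_severe_cluster(chart(rows), CFG) == T0


def test_severe_qualifies_at_first_reading_of_dense_window():
    rows = bp("a", T0 - 10 * 60, 165, 105)  # lone earlier severe reading
    for k in range(7):
        rows += bp("a", T0 + 10 * k, 170, 108)
    assert find_severe_cluster(chart(rows), CFG) == T0


# ---------------------------------------------------------------------------
# criteria 3-4: ICD lookups with family-prefix matching


def test_icd_single_eclampsia_code_found():
    events = chart([ev("a", 240 * DAY, "icd", "O15")])
    assert find_icd(events, CFG.icd_eclampsia) == 240 * DAY


def test_icd_prefix_family_match():
    events = chart([ev("a", 240 * DAY, "icd", "O14.1")])
    assert find_icd(events, {"O14"}) == 240 * DAY


def test_icd_no_events_returns_none():
    events = chart([*bp("a", T0, 150, 95)])
    assert find_icd(events, CFG.icd_hellp) is None


def test_icd_empty_code_set_is_error():
    with pytest.raises(ValueError):
        find_icd(chart([ev("a", T0, "icd", "O15")]), set())


def test_icd_earliest_of_several():
    events = chart([ev("a", 250 * DAY, "icd", "642.6"),
                    ev("a", 240 * DAY, "icd", "O15")])
    assert find_icd(events, CFG.icd_eclampsia) == 240 * DAY


# ---------------------------------------------------------------------------
# criterion 5: crisis BP + support


def test_crisis_with_high_ast_qualifies():
    events = chart([*bp("a", T0, 175, 112), ev("a", T0 + 60, "lab", "AST", 80)])
    assert find_crisis_with_support(events, CFG) == T0


def test_crisis_with_normal_lfts_and_no_icd_fails():
    events = chart([*bp("a", T0, 175, 112), ev("a", T0 + 60, "lab", "AST", 50),
                    ev("a", T0 + 60, "lab", "ALT", 60)])
    assert find_crisis_with_support(events, CFG) is None


def test_high_ast_without_crisis_reading_fails():
    events = chart([*bp("a", T0, 150, 95), ev("a", T0 + 60, "lab", "AST", 80)])
    assert find_crisis_with_support(events, CFG) is None


def test_crisis_with_pe_family_icd_qualifies():
    events = chart([*bp("a", T0, 175, 112), ev("a", T0 + 600, "icd", "O11")])
    assert find_crisis_with_support(events, CFG) == T0


def test_crisis_ast_boundary_is_strict():
    events = chart([*bp("a", T0, 175, 112), ev("a", T0 + 60, "lab", "AST", 64)])
    assert find_crisis_with_support(events, CFG) is None


def test_crisis_require_both_lfts_flag():
    cfg = PhenotypeConfig(require_both_lfts=True)
    events = chart([*bp("a", T0, 175, 112), ev("a", T0 + 60, "lab", "AST", 80)])
    assert find_crisis_with_support(events, cfg) is None
    events2 = chart([*bp("a", T0, 175, 112), ev("a", T0 + 60, "lab", "AST", 80),
                     ev("a", T0 + 60, "lab", "ALT", 90)])
    assert find_crisis_with_support(events2, cfg) == T0


# ---------------------------------------------------------------------------
# whole-algorithm assignment


def test_assign_single_criterion_two_fires_at_first_severe_reading():
    rows = []
    for k in range(7):
        rows += bp("a", 230 * DAY + 10 * k, 165, 105)
    label = assign_phenotype(chart(rows), CFG)
    assert label.is_case and label.criterion_id == 2
    assert label.diagnosis_ga_minutes == 230 * DAY


def test_assign_pair_before_twenty_weeks_is_not_a_case():
    t = 120 * DAY
    events = chart([*bp("a", t, 150, 95), *bp("a", t + 5 * 60, 150, 95),
                    prot("a", t)])
    label = assign_phenotype(events, CFG)
    assert not label.is_case
    assert label.criterion_id is None and label.diagnosis_ga_minutes is None


def test_assign_healthy_control_chart():
    events = chart([*bp("a", 100 * DAY, 115, 72), *bp("a", 200 * DAY, 118, 74),
                    ev("a", 100 * DAY, "lab", "AST", 20)])
    label = assign_phenotype(events, CFG)
    assert not label.is_case


def test_assign_diagnosis_time_uses_earliest_proteinuria_after_20_weeks():
    t_prot = 205 * DAY
    events = chart([prot("a", t_prot), *bp("a", T0, 150, 95),
                    *bp("a", T0 + 5 * 60, 150, 95)])
    label = assign_phenotype(events, CFG)
    assert label.criterion_id == 1
    assert label.diagnosis_ga_minutes == t_prot


def test_assign_tie_break_prefers_lower_criterion():
    # HELLP and eclampsia codes at the same minute: criterion 3 wins
    events = chart([ev("a", 240 * DAY, "icd", "O14.1"),
                    ev("a", 240 * DAY, "icd", "O15")])
    label = assign_phenotype(events, CFG)
    assert label.criterion_id == 3


def test_assign_rejects_multiple_pregnancies():
    events = chart([*bp("a", T0, 150, 95), *bp("b", T0, 150, 95)])
    with pytest.raises(ValueError):
        assign_phenotype(events, CFG)


def test_icd_only_comparator():
    assert icd_only_label(chart([ev("a", T0, "icd", "O11")]), CFG)
    assert not icd_only_label(chart([*bp("a", T0, 175, 112)]), CFG)


def test_unsorted_events_rejected_by_criteria():
    frame = pd.DataFrame(
        [*bp("a", T0 + 300, 150, 95), *bp("a", T0, 150, 95), prot("a", T0)],
        columns=["pregnancy_id", "ga_minutes", "kind", "code", "value", "units"],
    )
    with pytest.raises(ValueError):
        find_sustained_htn_with_proteinuria(frame, CFG)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence + monotonicity on random charts


def _brute_crit1(events, cfg, min_time=0):
    readings = bp_readings(events)
    exceeds = ((readings["sbp"] > cfg.bp_moderate[0])
               | (readings["dbp"] > cfg.bp_moderate[1]))
    times = readings.loc[exceeds, "ga_minutes"].to_numpy()
    labs = events[(events["kind"] == "lab") & (events["code"] == "URINE_PROT")]
    has_prot = bool((labs["value"] >= cfg.proteinuria_threshold).any())
    icd = events[events["kind"] == "icd"]
    has_prot = has_prot or any(
        any(str(c).startswith(p) for p in cfg.proteinuria_codes) for c in icd["code"]
    )
    if not has_prot:
        return None
    best = None
    for i in range(len(times)):
        for j in range(len(times)):
            if i != j and abs(times[j] - times[i]) >= cfg.moderate_gap_hours * 60:
                t = min(times[i], times[j])
                if t >= min_time and (best is None or t < best):
                    best = t
    return None if best is None else int(best)


def _brute_crit2(events, cfg, min_time=0):
    readings = bp_readings(events)
    exceeds = ((readings["sbp"] > cfg.bp_severe[0])
               | (readings["dbp"] > cfg.bp_severe[1]))
    times = np.sort(readings.loc[exceeds, "ga_minutes"].to_numpy())
    window = cfg.severe_window_hours * 60
    for t in times:
        if t < min_time:
            continue
        if ((times >= t) & (times <= t + window)).sum() >= cfg.severe_count:
            return int(t)
    return None


def _random_chart(rng) -> pd.DataFrame:
    n = int(rng.integers(1, 31))
    times = rng.choice(np.arange(190 * DAY, 260 * DAY, 7), size=n, replace=False)
    rows = []
    for t in times:
        kind = rng.choice(["bp", "prot", "icd", "lft"], p=[0.6, 0.15, 0.1, 0.15])
        if kind == "bp":
            sbp = float(rng.choice([120, 139, 140, 141, 150, 161, 165, 171, 175]))
            dbp = float(rng.choice([70, 89, 90, 91, 95, 101, 105, 111, 112]))
            rows += bp("p", t, sbp, dbp)
        elif kind == "prot":
            rows.append(ev("p", t, "lab", "URINE_PROT", float(rng.choice([0.1, 0.3, 0.6]))))
        elif kind == "icd":
            code = str(rng.choice(["O11", "O14.1", "O15", "642.4", "Z34", "R80"]))
            rows.append(ev("p", t, "icd", code))
        else:
            rows.append(ev("p", t, "lab", str(rng.choice(["AST", "ALT"])),
                           float(rng.choice([30, 64, 65, 80]))))
    return chart(rows)


def test_criteria_match_brute_force_on_random_charts():
    rng = np.random.default_rng(202)
    for _ in range(300):
        events = _random_chart(rng)
        assert find_sustained_htn_with_proteinuria(events, CFG) == _brute_crit1(events, CFG)
        assert find_severe_cluster(events, CFG) == _brute_crit2(events, CFG)


def test_monotonicity_removing_events_never_creates_a_case():
    rng = np.random.default_rng(77)
    for _ in range(60):
        events = _random_chart(rng)
        label = assign_phenotype(events, CFG)
        drop = rng.random(len(events)) < 0.3
        # drop SBP/DBP jointly so readings stay paired
        minutes_dropped = set(events.loc[drop, "ga_minutes"])
        sub = events[~events["ga_minutes"].isin(minutes_dropped)].reset_index(drop=True)
        sub_label = assign_phenotype(sub, CFG)
        if not label.is_case:
            assert not sub_label.is_case


def test_censoring_before_diagnosis_reverts_to_control(cohort_2k, labels_2k):
    cases = labels_2k[labels_2k["is_case"]].head(25)
    for row in cases.itertuples(index=False):
        ev_one = cohort_2k.events[cohort_2k.events["pregnancy_id"] == row.pregnancy_id]
        trimmed = ev_one[ev_one["ga_minutes"] < row.diagnosis_ga_minutes]
        assert not assign_phenotype(trimmed, CFG).is_case
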