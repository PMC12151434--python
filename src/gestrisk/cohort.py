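"""Leak-free per-timepoint dataset construction and patient-level splits.

A prediction at gestational week *t* may only use events time-stamped on or
before *t* (boundary inclusive: a measurement taken at the visit that
anchors the timepoint is available at that visit).  Pregnancies that have
already delivered, or already carry a preeclampsia diagnosis, strictly
before week *t* are excluded from the week-*t* dataset — there is nothing
left to predict for them.  The eventual case status is the label.

Train/test partitioning is by *patient*, not pregnancy: every pregnancy of
a patient lands on the same side, so repeat pregnancies can never leak
information across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeaturePipeline, FeatureSpec

__all__ = [
    "CensoredDataset",
    "censor_events",
    "build_timepoint_dataset",
    "split_by_patient",
    "verify_no_leakage",
]

_MINUTES_PER_DAY = 1440
_GROUP_COLUMNS = ["self_reported_race", "ethnicity", "insurance"]


@dataclass
class CensoredDataset:
    """Feature matrix, labels and group attributes at one censor timepoint."""

    timepoint_weeks: float
    X: pd.DataFrame           # rows indexed by pregnancy_id
    y: pd.Series              # eventual case status, aligned with X
    groups: pd.DataFrame      # race / ethnicity / insurance, aligned with X
    censor_ga_minutes: int
    provenance: dict[str, FeatureSpec] = field(default_factory=dict)
    pipeline: FeaturePipeline | None = None
    pregnancies: pd.DataFrame | None = None  # static rows used to build X

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("matrix, labels and groups must align row-wise")
        if not (self.X.index.equals(self.y.index) and self.X.index.equals(self.groups.index)):
            raise ValueError("matrix, labels and groups must share an index")


def censor_events(events: pd.DataFrame, timepoint_weeks: float) -> pd.DataFrame:
    """Keep exactly the events with ga_minutes <= timepoint (inclusive)."""
    if not np.isfinite(timepoint_weeks) or timepoint_weeks <= 0:
        raise ValueError(f"invalid censor timepoint: {timepoint_weeks!r}")
    cutoff = int(timepoint_weeks * 7 * _MINUTES_PER_DAY)
    return events[events["ga_minutes"] <= cutoff]


def build_timepoint_dataset(
    pregnancies: pd.DataFrame,
    events: pd.DataFrame,
    labels: pd.DataFrame,
    timepoint_weeks: float,
    feature_pipeline: FeaturePipeline,
) -> CensoredDataset:
    """Assemble the week-``timepoint_weeks`` dataset.

    ``labels`` must come from the phenotype applied to *uncensored* events
    (columns pregnancy_id, is_case, diagnosis_ga_minutes).  Exclusion uses
    strict comparison in days: delivery or diagnosis before the timepoint
    removes the row; a delivery or diagnosis exactly on the boundary day is
    retained.
    """
    merged = pregnancies.merge(labels, on="pregnancy_id", how="left", validate="one_to_one")
    if merged["is_case"].isna().any():
        missing = merged.loc[merged["is_case"].isna(), "pregnancy_id"].tolist()[:5]
        raise ValueError(f"labels missing for pregnancies, e.g. {missing}")

    cutoff_days = timepoint_weeks * 7.0
    delivered_before = merged["delivery_ga_days"] < cutoff_days
    diag_days = merged["diagnosis_ga_minutes"] / _MINUTES_PER_DAY
    diagnosed_before = merged["is_case"].astype(bool) & (diag_days < cutoff_days)
    keep = merged[~delivered_before & ~diagnosed_before].reset_index(drop=True)

    censored = censor_events(events, timepoint_weeks)
    censored = censored[censored["pregnancy_id"].isin(set(keep["pregnancy_id"]))]
    X = feature_pipeline.transform(keep, censored, timepoint_weeks)
    y = pd.Series(keep["is_case"].astype(bool).to_numpy(), index=X.index, name="is_case")
    groups = keep.set_index("pregnancy_id")[_GROUP_COLUMNS].loc[X.index]
    return CensoredDataset(
        timepoint_weeks=timepoint_weeks,
        X=X,
        y=y,
        groups=groups,
        censor_ga_minutes=int(timepoint_weeks * 7 * _MINUTES_PER_DAY),
        provenance=feature_pipeline.provenance(timepoint_weeks),
        pipeline=feature_pipeline,
        pregnancies=keep,
    )


def split_by_patient(
    pregnancies: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Partition pregnancies into development and test sets by patient.

    All pregnancies of a patient fall on the same side.  Patients are
    shuffled with the given seed and assigned to the test side until its
    pregnancy share reaches ``test_fraction`` (within +/-2% for realistic
    family sizes).  Returns (dev_pregnancy_ids, test_pregnancy_ids).
    """
    rng = np.random.default_rng(seed)
    counts = pregnancies.groupby("patient_id")["pregnancy_id"].count()
    patients = counts.index.to_numpy()
    order = rng.permutation(len(patients))
    target = test_fraction * len(pregnancies)
    test_patients = set()
    total = 0
    for i in order:
        if total >= target:
            break
        test_patients.add(patients[i])
        total += int(counts.iloc[i])
    mask = pregnancies["patient_id"].isin(test_patients)
    return (
        pd.Index(pregnancies.loc[~mask, "pregnancy_id"]),
        pd.Index(pregnancies.loc[mask, "pregnancy_id"]),
    )


def verify_no_leakage(dataset: CensoredDataset, raw_events: pd.DataFrame) -> pd.DataFrame:
    """Recompute every feature from censored events and flag any discrepancy.

    The dataset's own matrix is compared bit-for-bit against a fresh
    featurization of ``raw_events`` censored at the dataset's timepoint.
    Any feature whose stored value differs from the recomputation (beyond
    NaN agreement) is reported; an honest pipeline yields an empty report.
    """
    if dataset.pipeline is None or dataset.pregnancies is None:
        raise ValueError("dataset lacks provenance needed for verification")
    censored = censor_events(raw_events, dataset.timepoint_weeks)
    censored = censored[censored["pregnancy_id"].isin(set(dataset.X.index))]
    fresh = dataset.pipeline.transform(
        dataset.pregnancies, censored, dataset.timepoint_weeks
    )
    fresh = fresh.loc[dataset.X.index, dataset.X.columns]
    stored = dataset.X
    same = (stored.to_numpy() == fresh.to_numpy()) | (
        stored.isna().to_numpy() & fresh.isna().to_numpy()
    )
    rows, cols = np.where(~same)
    return pd.DataFrame(
        {
            "pregnancy_id": stored.index[rows],
            "feature": stored.columns[cols],
            "stored": stored.to_numpy()[rows, cols],
            "recomputed": fresh.to_numpy()[rows, cols],
        }
    )
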