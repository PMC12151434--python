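"""Shared fixtures: event-chart builders and session-scoped synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gestrisk.phenotyping import PhenotypeConfig, phenotype_cohort
from gestrisk.synthetic import GeneratorConfig, generate_cohort

EVENT_COLUMNS = ["pregnancy_id", "ga_minutes", "kind", "code", "value", "units"]

DAY = 1440


def ev(pid, minutes, kind, code, value=np.nan, units=""):
    return (pid, int(minutes), kind, code, value, units)


def bp(pid, minutes, sbp, dbp):
    return [
        ev(pid, minutes, "vital", "SBP", sbp, "mmHg"),
        ev(pid, minutes, "vital", "DBP", dbp, "mmHg"),
    ]


def chart(rows) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return frame.sort_values("ga_minutes", kind="mergesort").reset_index(drop=True)


@pytest.fixture(scope="session")
def pheno_cfg() -> PhenotypeConfig:
    return PhenotypeConfig()


@pytest.fixture(scope="session")
def cohort_2k():
    return generate_cohort(GeneratorConfig(n_pregnancies=2000, seed=7))


@pytest.fixture(scope="session")
def labels_2k(cohort_2k):
    return phenotype_cohort(cohort_2k.events)


@pytest.fixture(scope="session")
def cohort_5k():
    return generate_cohort(GeneratorConfig(n_pregnancies=5000, seed=11))


@pytest.fixture(scope="session")
def labels_5k(cohort_5k):
    return phenotype_cohort(cohort_5k.events)
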