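import dataclasses

import numpy as np
import pytest

from melanoma_shields.cohort_model import Cohort, PatientRecord
from melanoma_shields.synthetic_cohort import generate_cohort, reference_cohort_config


def make_record(patient_id="P1", group="metastatic", lvd_total=10.0, lvi=True,
                breslow_mm=2.0, followup_months=72.0, **kw) -> PatientRecord:
    return PatientRecord(
        patient_id=patient_id,
        group=group,
        lvd_total=lvd_total,
        lvi=lvi,
        breslow_mm=breslow_mm,
        followup_months=followup_months,
        **kw,
    )


@pytest.fixture
def toy_cohort() -> Cohort:
    """Six valid patients, three per outcome group, hand-checkable."""
    return Cohort(
        [
            make_record("M1", "metastatic", 10.0, True, 2.0),
            make_record("M2", "metastatic", 12.0, True, 3.0),
            make_record("M3", "metastatic", 8.0, False, 2.5),
            make_record("N1", "non_metastatic", 6.0, False, 1.5),
            make_record("N2", "non_metastatic", 4.0, False, 2.0),
            make_record("N3", "non_metastatic", 7.0, True, 1.0),
        ],
        provenance="toy",
    )


@pytest.fixture(scope="session")
def large_cohort():
    """One 100k-per-group synthetic cohort shared by the slow
    large-sample checks."""
    cfg = reference_cohort_config(seed=20260928)
    cfg = dataclasses.replace(
        cfg,
        metastatic=dataclasses.replace(cfg.metastatic, n=100_000),
        non_metastatic=dataclasses.replace(cfg.non_metastatic, n=100_000),
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
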