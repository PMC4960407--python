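import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import icdrisk as ir
from icdrisk import evaluation as ev

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

PAPER_LIKE_SEED = 7
NULL_SEED = 11


@pytest.fixture
def toy_cohort():
    """Three patients, hand-countable diagnosis histories."""
    assessments = pd.DataFrame(
        {
            "assessment_id": ["A1", "A2", "A3"],
            "patient_id": ["P1", "P2", "P3"],
            "assessment_date": ["2011-06-01", "2011-06-01", "2011-06-01"],
            "clinical_score": [2, 3, 0],
            "outcome": [0, 1, 0],
        }
    )
    diagnoses = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P1", "P2", "P2", "P3"],
            "diagnosis_date": [
                "2011-05-30",  # 2 days before -> window 1
                "2011-02-21",  # 100 days -> window 3
                "2010-04-27",  # 400 days -> window 4
                "2011-06-01",  # same day -> excluded by half-open bound
                "2011-05-01",  # 31 days -> window 1
                "2011-05-01",
            ],
            "icd10_code": ["A09", "B20.1", "A41", "I10", "F32.1", "Z50.1"],
        }
    )
    return assessments, diagnoses


def _evaluated_subset(cohort):
    F = ir.frequency_matrix(cohort.assessments, cohort.diagnoses)
    keep = F.clinical > 0
    return F, ir.FrequencyMatrix(
        values=F.values[keep],
        assessment_ids=F.assessment_ids[keep],
        labels=F.labels[keep],
        patient_ids=F.patient_ids[keep],
        clinical=F.clinical[keep],
    )


@pytest.fixture(scope="session")
def paper_like():
    """Full-size calibrated cohort plus its cross-validated evaluation."""
    cfg = ir.calibrate_preset(seed=PAPER_LIKE_SEED, n_assessments=16858)
    cohort = ir.generate_cohort(cfg)
    F, sub = _evaluated_subset(cohort)
    plan = ev.make_folds(sub.n_assessments, k=10, seed=PAPER_LIKE_SEED)
    report = ev.cross_validate(sub, sub.clinical, sub.labels, plan)
    return {"config": cfg, "cohort": cohort, "F": F, "report": report}


@pytest.fixture(scope="session")
def null_like():
    """No-signal cohort (both groups share the control process) and its evaluation."""
    cfg = ir.null_preset(seed=NULL_SEED, n_assessments=5000)
    cohort = ir.generate_cohort(cfg)
    F, sub = _evaluated_subset(cohort)
    plan = ev.make_folds(sub.n_assessments, k=10, seed=NULL_SEED)
    report = ev.cross_validate(sub, sub.clinical, sub.labels, plan)
    return {"config": cfg, "cohort": cohort, "F": F, "report": report}


def random_frequency_matrix(rng, n, max_count=30, with_labels=True):
    """Small random FrequencyMatrix with nested windows (cumulative counts)."""
    per_level = rng.integers(0, max_count // 5 + 1, size=(n, 5, 18))
    values = np.cumsum(per_level, axis=1)
    labels = None
    if with_labels:
        labels = rng.integers(0, 2, size=n)
        labels[0], labels[1] = 0, 1  # both groups present
    return ir.FrequencyMatrix(
        values=values,
        assessment_ids=np.arange(n),
        labels=labels,
    )
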