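import numpy as np
import pandas as pd
import pytest

from csvdstrat import ClassificationConfig, build_table1_fixture, classify_cohort

FIXED = ClassificationConfig(threshold_mode="fixed", fixed_threshold=0.0007)


@pytest.fixture(scope="session")
def fixture_cohort() -> pd.DataFrame:
    return build_table1_fixture()


@pytest.fixture(scope="session")
def fixture_results(fixture_cohort):
    results, summary = classify_cohort(fixture_cohort, FIXED)
    return results, summary


def make_subject(
    wmh_ratio=0.0003,
    lacune=0,
    lobar=0,
    deep=0,
    infra=0,
    followup=5.0,
    died=0,
    subject_id="s1",
    age=65.0,
    sex="female",
    tiv=1400.0,
) -> dict:
    """Minimal valid subject record for single-record classification tests."""
    return {
        "subject_id": subject_id,
        "age_years": age,
        "sex": sex,
        "hypertension": 0,
        "diabetes": 0,
        "dyslipidemia": 0,
        "smoking": 0,
        "sbp_mmhg": 120.0,
        "ldl_mg_dl": 110.0,
        "hba1c_pct": 5.6,
        "wmh_volume_ml": wmh_ratio * tiv,
        "tiv_ml": tiv,
        "lacune_count": lacune,
        "cmb_lobar": lobar,
        "cmb_deep": deep,
        "cmb_infratentorial": infra,
        "followup_years": followup,
        "died": died,
    }


def make_cohort(records) -> pd.DataFrame:
    df = pd.DataFrame(records)
    df["subject_id"] = [f"s{i:04d}" for i in range(len(df))]
    return df


def make_survival_frame(times, events, x) -> pd.DataFrame:
    """Two-column survival dataset with a generic binary exposure ``x``."""
    return pd.DataFrame(
        {
            "subject_id": [f"t{i}" for i in range(len(times))],
            "followup_years": np.asarray(times, dtype=float),
            "died": np.asarray(events, dtype=int),
            "x": np.asarray(x),
        }
    )
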