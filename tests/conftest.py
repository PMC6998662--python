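import pytest

import serumrna as sr


def make_case(i, age=55.0, sex="male", bdg="BDg_A", smoking="current",
              stage="advanced", histology="NSCLC", t=60.0):
    return sr.SampleRecord(
        sample_id=f"case{i:03d}", subject_id=f"P{i:03d}", group="case", sex=sex,
        age_at_donation=age, bdg=bdg, smoking=smoking, stage=stage,
        histology=histology, time_to_diagnosis=t,
    )


def make_control(i, age=50.0, sex="male", bdg="BDg_A", smoking="former"):
    return sr.SampleRecord(
        sample_id=f"ctrl{i:03d}", subject_id=f"C{i:03d}", group="control", sex=sex,
        age_at_donation=age, bdg=bdg, smoking=smoking,
    )


@pytest.fixture(scope="session")
def cfg():
    return sr.StudyConfig()


@pytest.fixture(scope="session")
def small_cohort(cfg):
    """Null cohort at 20% scale, 40 RNAs: fast, covers all covariate levels."""
    margins = sr.CohortMargins().scaled(0.2)
    return sr.generate_cohort(cfg, margins=margins, n_rnas=40, seed=12345)


@pytest.fixture(scope="session")
def full_null_cohort(cfg):
    """Null cohort at the default study margins (1061 samples), 120 RNAs."""
    return sr.generate_cohort(cfg, n_rnas=120, seed=777)
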