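import numpy as np
import pytest

from matuscore import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20210219)


@pytest.fixture(scope="session")
def cll_template():
    return simulate.default_case_designs()["CLL-typical"][0]


@pytest.fixture(scope="session")
def mcl_template():
    return simulate.default_case_designs()["MCL"][0]


@pytest.fixture(scope="session")
def cll_sample():
    """One simulated typical-CLL sample at a realistic event count."""
    tpl = simulate.default_case_designs()["CLL-typical"][0]
    rng = np.random.default_rng(11)
    profile = simulate.sample_patient_profile(tpl, rng, sample_id="CLL-fixture")
    bundle = simulate.generate_events(profile, 20_000, rng)
    return profile, bundle


@pytest.fixture(scope="session")
def small_cohort_run():
    """A small but two-class cohort processed end to end in memory."""
    from matuscore import pipeline

    cfg = pipeline.RunConfig(
        composition={
            "CLL-typical": 6,
            "CLL-atypical": 2,
            "MCL": 4,
            "MZL": 3,
            "HCL": 2,
        },
        events_per_sample=4000,
        master_seed=5,
    )
    return pipeline.run_cohort(cfg)
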