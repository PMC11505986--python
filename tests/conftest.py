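import numpy as np
import pytest

from tallysurv import (
    Cohort,
    PatientRecord,
    SimulationConfig,
    VisitRecord,
    simulate_cohort,
)


def make_patient(pid="P1", stage="I", er="+", pr="+", duration=365.0, event=1,
                 age_dx=72.0, comorbidity_dx=2.0, **kw):
    defaults = dict(race="white", marital="married", grade="2",
                    laterality="left", her2="-")
    defaults.update(kw)
    return PatientRecord(patient_id=pid, age_dx=age_dx, stage=stage, er=er, pr=pr,
                         comorbidity_dx=comorbidity_dx, duration=duration,
                         event=event, **defaults)


def make_visit(pid="P1", t=10.0, age=72.0, comorbidity=2.0,
               treatments=(), adverse_events=()):
    return VisitRecord(patient_id=pid, t=t, age=age, comorbidity_index=comorbidity,
                       treatments=frozenset(treatments),
                       adverse_events=frozenset(adverse_events))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def six_scenario_cohort():
    """One patient per prognostic scenario plus one with unknown receptors."""
    patients = [
        make_patient("A", stage="I", er="+", pr="+"),
        make_patient("B", stage="II", er="+", pr="-"),
        make_patient("C", stage="III", er="-", pr="+"),
        make_patient("D", stage="I", er="-", pr="-"),
        make_patient("E", stage="II", er="-", pr="-"),
        make_patient("F", stage="III", er="-", pr="-"),
        make_patient("G", stage="I", er="unknown", pr="unknown"),
    ]
    visits = [make_visit(p.patient_id, t=5.0) for p in patients]
    return Cohort.from_records(patients, visits)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort with time-varying effects, shared across tests."""
    cfg = SimulationConfig.designed_separation(n=300, seed=7)
    cfg.admin_censor_time = 24
    return simulate_cohort(cfg)
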