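import numpy as np
import pytest

from lumbarcpr import (
    AssessmentTime,
    Cohort,
    DirectionHint,
    PatientRecord,
    Scale,
    VariableClass,
    VariableSpec,
)


def make_patient(pid, odi_t0, odi_t8, odi_t34=None, sex="F", age=45.0, bmi=26.0,
                 nprs_t0=5.0, nprs_t8=2.5, predictors=None):
    odi = {AssessmentTime.T0: odi_t0}
    if odi_t8 is not None:
        odi[AssessmentTime.T8] = odi_t8
    if odi_t34 is not None:
        odi[AssessmentTime.T34] = odi_t34
    return PatientRecord(
        id=pid, sex=sex, age=age, bmi=bmi, odi=odi,
        nprs={AssessmentTime.T0: nprs_t0, AssessmentTime.T8: nprs_t8},
        predictors=predictors or {},
    )


@pytest.fixture
def tiny_cohort():
    """Six hand-built patients: 3 successes, 1 improvement, 2 failures at T8."""
    variables = [
        VariableSpec("reach", VariableClass.A, Scale.CONTINUOUS,
                     DirectionHint.HIGH_IS_POSITIVE),
        VariableSpec("laxity", VariableClass.A, Scale.ORDINAL,
                     DirectionHint.LOW_IS_POSITIVE),
    ]
    patients = [
        make_patient("p1", 27.0, 7.0, predictors={"reach": 0.80, "laxity": 2.0}),
        make_patient("p2", 30.0, 12.0, predictors={"reach": 0.78, "laxity": 3.0}),
        make_patient("p3", 40.0, 18.0, predictors={"reach": 0.75, "laxity": 6.0}),
        make_patient("p4", 36.0, 21.0, predictors={"reach": 0.70, "laxity": 4.0}),
        make_patient("p5", 24.0, 22.0, predictors={"reach": 0.60, "laxity": 7.0}),
        make_patient("p6", 20.0, 18.0, predictors={"reach": 0.55, "laxity": None}),
    ]
    return Cohort(patients=patients, variables=variables).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
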