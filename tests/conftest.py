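import numpy as np
import pytest

from mwrisk import Thermogram


def make_thermogram(
    skin_right=None,
    skin_left=None,
    int_right=None,
    int_left=None,
    skin_ref=None,
    int_ref=None,
    patient_id="t",
    visit_date="2022-01-01",
):
    """Thermogram with constant defaults; pass arrays to override channels."""
    const = lambda v, n=10: np.full(n, float(v))
    return Thermogram(
        patient_id=patient_id,
        visit_date=visit_date,
        t_skin_right=np.asarray(skin_right, float) if skin_right is not None else const(31.0),
        t_skin_left=np.asarray(skin_left, float) if skin_left is not None else const(31.0),
        t_int_right=np.asarray(int_right, float) if int_right is not None else const(34.0),
        t_int_left=np.asarray(int_left, float) if int_left is not None else const(34.0),
        t_skin_ref=np.asarray(skin_ref, float) if skin_ref is not None else const(31.0, 2),
        t_int_ref=np.asarray(int_ref, float) if int_ref is not None else const(34.0, 2),
    )


def random_thermogram(rng: np.random.Generator) -> Thermogram:
    """Uniform random temperatures in a plausible clinical window."""
    u = lambda n=10: rng.uniform(29.0, 38.0, n)
    return Thermogram(
        patient_id="rand",
        visit_date="2022-01-01",
        t_skin_right=u(),
        t_skin_left=u(),
        t_int_right=u(),
        t_int_left=u(),
        t_skin_ref=u(2),
        t_int_ref=u(2),
    )


@pytest.fixture
def symmetric_exam():
    return make_thermogram()


@pytest.fixture
def rng():
    return np.random.default_rng(20221230)
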