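import numpy as np
import pytest

from fotscreen.fot_data import FotRecord, _COLUMN_TO_ITEM, complete_derived
from fotscreen.synthetic_cohort import default_spec, generate_cohort


def make_record(subject_id="s1", sex="male", group="control", **phase_values):
    """Build a completed record from phase-column keyword values.

    Defaults are round numbers near healthy adult male magnitudes.
    """
    defaults = {
        "R5_in": 2.0, "R5_ex": 2.4, "R20_in": 1.9, "R20_ex": 2.1,
        "X5_in": -0.2, "X5_ex": -0.1, "Fres_in": 6.5, "Fres_ex": 6.0,
        "ALX_in": 1.0, "ALX_ex": 0.8,
    }
    defaults.update(phase_values)
    values = {_COLUMN_TO_ITEM[k]: v for k, v in defaults.items()}
    return complete_derived(
        FotRecord(subject_id=subject_id, sex=sex, group=group, values=values, age=40.0)
    )


@pytest.fixture(scope="session")
def small_control_cohort():
    """300 male controls from the default generative spec (seeded)."""
    return generate_cohort(default_spec("male", "control", n=300), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
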