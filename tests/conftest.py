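import numpy as np
import pandas as pd
import pytest

from roughdelphi.simulate import (
    consistent_survey_spec,
    generate_survey,
    study_survey_spec,
)
from roughdelphi.table import DecisionTable


@pytest.fixture
def four_object_table() -> DecisionTable:
    """a determines d perfectly; b is pure noise."""
    return DecisionTable(
        pd.DataFrame({"a": [1, 1, 2, 2], "b": [1, 2, 1, 2], "d": [1, 1, 2, 2]}),
        decision="d",
    )


@pytest.fixture(scope="session")
def study_table() -> DecisionTable:
    """The study-shaped 163-respondent fixture with planted rules."""
    return generate_survey(study_survey_spec(seed=1))


@pytest.fixture(scope="session")
def consistent_table() -> DecisionTable:
    """A 163-respondent table whose profile determines the decision."""
    return generate_survey(consistent_survey_spec(seed=1))


def random_table(
    rng: np.random.Generator,
    max_objects: int = 50,
    max_attrs: int = 6,
    max_values: int = 4,
) -> DecisionTable:
    """A random small categorical decision table for oracle comparisons."""
    n = int(rng.integers(4, max_objects + 1))
    n_attrs = int(rng.integers(1, max_attrs + 1))
    n_vals = int(rng.integers(2, max_values + 1))
    data = {
        f"c{i}": rng.integers(1, n_vals + 1, size=n) for i in range(n_attrs)
    }
    data["d"] = rng.integers(1, int(rng.integers(2, 4)) + 1, size=n)
    return DecisionTable(pd.DataFrame(data), decision="d")
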