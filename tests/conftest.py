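import numpy as np
import pytest

from lintgrade.model_core import HyperParams
from lintgrade.synthetic_data import (
    CULTIVAR_COUNTS,
    make_grade_model,
    synthesize_feature_table,
)

FAST_HP = HyperParams(n_trees=30, max_depth=12)


@pytest.fixture(scope="session")
def grade_model():
    """Default 7-grade appearance model at the calibrated separation."""
    return make_grade_model(n_grades=7, seed=1)


@pytest.fixture(scope="session")
def small_table(grade_model):
    """A small balanced feature table: 30 records per grade, 7 grades."""
    return synthesize_feature_table(grade_model, [30] * 7, seed=2)


@pytest.fixture(scope="session")
def separable_table():
    """Widely separated grades: any reasonable classifier is near-perfect."""
    model = make_grade_model(n_grades=7, separation=6.0, seed=3)
    return synthesize_feature_table(model, [50] * 7, seed=3)


@pytest.fixture(scope="session")
def giza86_counts():
    return [c for c in CULTIVAR_COUNTS["Giza 86"] if c > 0]
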