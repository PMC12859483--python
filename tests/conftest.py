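import numpy as np
import pytest

from ploidymapper.feature_io import FeatureTable, NucleusRecord
from ploidymapper.mixture import FitParams


@pytest.fixture
def fast_params():
    """Small EM hyperparameters for test-sized data."""
    return FitParams(tol=1e-6, max_iter=500, n_init=4, seed=0)


def make_table(rows):
    """Build a FeatureTable from dicts of NucleusRecord fields."""
    records = []
    for i, row in enumerate(rows):
        row = dict(row)
        row.setdefault("object_id", i + 1)
        row.setdefault("total_intensity", 100.0)
        row.setdefault("size", 10.0)
        records.append(NucleusRecord(**row))
    return FeatureTable(records=records)


@pytest.fixture
def small_table():
    return make_table(
        [
            {"total_intensity": 100.0, "size": 10.0, "user_label": "nucleus",
             "variance_of_intensity": 5.0, "group": "a"},
            {"total_intensity": 220.0, "size": 11.0, "user_label": "nucleus",
             "variance_of_intensity": 50.0, "group": "a"},
            {"total_intensity": 440.0, "size": 22.0, "user_label": "incomplete",
             "variance_of_intensity": 500.0, "group": "b"},
            {"total_intensity": 800.0, "size": 40.0, "user_label": "nucleus",
             "variance_of_intensity": 5000.0, "group": "b"},
        ]
    )
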