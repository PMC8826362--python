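import numpy as np
import pandas as pd
import pytest

from qolnet.cohort import CohortTable, ScaleDefinition


def make_table(values: dict, scale_defs=None, timepoints=("M0", "M12")):
    """Build a small CohortTable from {scale: {(subject, tp): value}} dicts."""
    scales = list(values)
    subjects = sorted({k for col in values.values() for k in col})
    idx = pd.MultiIndex.from_tuples(subjects, names=["subject_id", "timepoint"])
    data = pd.DataFrame(index=idx)
    for s in scales:
        data[s] = [values[s].get(k, np.nan) for k in subjects]
    if scale_defs is None:
        scale_defs = [ScaleDefinition(s, "continuous", (0.0, 100.0)) for s in scales]
    return CohortTable(data, scale_defs, timepoint_order=list(timepoints))


@pytest.fixture
def continuous_defs_15():
    """Fifteen wide continuous scales (negligible clipping)."""
    return [
        ScaleDefinition(f"scale_{i:02d}", "continuous", (0.0, 100.0),
                        mean=50.0, sd=10.0)
        for i in range(15)
    ]


@pytest.fixture
def small_cohort():
    """3 subjects x 2 scales x 2 timepoints, fully observed."""
    vals = {
        "global_qol": {
            ("A", "M0"): 60.0, ("A", "M12"): 70.0,
            ("B", "M0"): 50.0, ("B", "M12"): 55.0,
            ("C", "M0"): 80.0, ("C", "M12"): 85.0,
        },
        "fatigue": {
            ("A", "M0"): 40.0, ("A", "M12"): 50.0,
            ("B", "M0"): 30.0, ("B", "M12"): 35.0,
            ("C", "M0"): 70.0, ("C", "M12"): 75.0,
        },
    }
    return make_table(vals)
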