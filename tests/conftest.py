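import numpy as np
import pandas as pd
import pytest

from matchboot.data_model import CohortTable, default_schema
from matchboot.synthetic_cohort import SimulationConfig, generate_cohort

# reasonable in-range defaults for hand-built rows
_DEFAULTS = {
    "age": 70.0, "female_sex": 0, "hospital": "site_a", "outpatient": 0,
    "heart_rate": 95.0, "respiratory_rate": 22.0, "systolic_bp": 130.0,
    "body_temperature": 37.4, "hematocrit": 37.0, "bun": 18.0,
    "sodium": 138.0, "glucose": 130.0, "albumin": 3.5,
    "sputum_cfu": 1e4, "sputum_semiquant": 0.0,
}


def make_cohort(rows: list[dict], spec=None) -> CohortTable:
    """Build a small valid cohort from partial row dicts.

    Unspecified covariates default to benign in-range values; unspecified
    metadata defaults to a recovered inpatient observed for 10 days.
    """
    spec = spec if spec is not None else default_schema()
    full = []
    for i, row in enumerate(rows):
        rec = {"id": f"T{i:03d}", "arm": "BL", "outcome": "recovery",
               "obs_days": 10.0, "los_days": 10.0, "abx_days": 5.0}
        for s in spec:
            rec[s.name] = _DEFAULTS.get(s.name, 0.0 if s.kind != "categorical" else s.levels[0])
        rec.update(row)
        if rec.get("outpatient") == 1:
            rec["los_days"] = np.nan
        full.append(rec)
    return CohortTable(spec=list(spec), df=pd.DataFrame(full))


@pytest.fixture(scope="session")
def small_cohort():
    """Complete synthetic cohort, n=400, no missingness."""
    cohort, truth = generate_cohort(SimulationConfig(n=400, seed=101, miss_probs={}))
    return cohort, truth


@pytest.fixture(scope="session")
def masked_cohort():
    """Default generator cohort with MAR missingness, n=500."""
    cohort, truth = generate_cohort(SimulationConfig(n=500, seed=202))
    return cohort, truth
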