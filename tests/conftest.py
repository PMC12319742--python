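import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import taucut as tc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def toy_frame() -> pd.DataFrame:
    """Six participants, three MTL regions, handmade values."""
    regions = {"entorhinal": 3500.0, "parahippocampal": 4100.0, "amygdala": 3100.0}
    base = [
        # id, dx, group, age, sex, edu, amyloid, suvr level
        ("P1", "CU", "Hispanic", 62.0, "F", 12.0, 0.95, 1.05),
        ("P2", "CU", "NHW", 65.0, "M", 16.0, 1.00, 1.10),
        ("P3", "CU", "NHB", 60.0, "F", 14.0, 1.10, 1.15),
        ("P4", "MCI", "NHW", 71.0, "M", 15.0, 1.30, 1.45),
        ("P5", "MCI", "Hispanic", 69.0, "F", 11.0, 1.05, 1.20),
        ("P6", "AD", "NHB", 75.0, "M", 13.0, 1.40, 1.60),
    ]
    rows = []
    for pid, dx, grp, age, sex, edu, amy, level in base:
        row = {
            "participant_id": pid,
            "diagnosis": dx,
            "ethnoracial_group": grp,
            "age": age,
            "sex": sex,
            "education": edu,
            "global_amyloid_suvr": amy,
        }
        for i, (region, vol) in enumerate(regions.items()):
            row[f"suvr_mean__{region}"] = level + 0.01 * i
            row[f"suvr_median__{region}"] = level + 0.01 * i + 0.005
            row[f"vol__{region}"] = vol
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_cohort() -> tc.Cohort:
    return tc.Cohort(toy_frame())


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-like synthetic cohort, shared across tests (seed 7)."""
    cohort, truth = tc.generate(tc.default_habs_like_config(seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def primary_contrast(default_cohort):
    """(sub-cohort, labels, mtl scores) for the amyloid-stratified CU-vs-CI contrast."""
    cohort, _ = default_cohort
    sub, labels = tc.select_contrast(cohort, "cu-vs-ci", amyloid_stratified=True)
    scores = tc.roi_scores(sub, "mtl_composite")
    return sub, labels, scores
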