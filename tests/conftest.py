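import warnings

import pandas as pd
import pytest

from otoprov import profile_windows, provenance
from otoprov.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full synthetic cohort under the default study conditions (seed 1)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def stage_table(default_cohort):
    """Acid-corrected stage values joined to sample metadata."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = profile_windows.apply_acid_correction(default_cohort.as_dataset())
        sv = profile_windows.extract_stage_values(corrected)
    return provenance.merge_stage_with_samples(sv, default_cohort.samples)


@pytest.fixture(scope="session")
def labeled_table(stage_table):
    """Stage table after the threshold rule."""
    rules = provenance.compute_thresholds(stage_table)
    return provenance.assign_by_threshold(stage_table, rules)


@pytest.fixture(scope="session")
def truth_by_fish(default_cohort) -> pd.Series:
    return default_cohort.truth.set_index("fish_id")["true_label"]
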