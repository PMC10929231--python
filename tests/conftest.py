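import numpy as np
import pandas as pd
import pytest

import resiliome as r


@pytest.fixture(scope="session")
def small_design():
    """6-subject design on the default schedule, no missingness."""
    return r.generate_design(6, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact perturbed cohort: 6 subjects, all tables."""
    return r.simulate_cohort(n_subjects=6, seed=3, missingness_rate=0.05)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return r.run_pipeline(
        small_cohort["samples"], small_cohort["scalars"], small_cohort["profiles"]
    )


def make_distance_frame(rows):
    """Helper: distance frames from (day, time, change, raw, norm) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "nominal_day",
            "collection_time",
            "change",
            "raw_distance",
            "normalised_distance",
        ],
    )
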