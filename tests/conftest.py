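import numpy as np
import pandas as pd
import pytest

from rbclink.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """A mid-sized cohort with every kind of planted structure."""
    cfg = SimConfig(
        seed=7,
        n_deficient=20,
        n_sufficient=20,
        n_variables_invivo=6,
        n_variables_exvivo=8,
        planted_edges=(("IV001", "EV001", 0.95),),
        planted_rewired_pairs=(("EV003", "EV004", 0.9, 0.2),),
        planted_signatures=(("SIG1", 0.95),),
        planted_group_effects=(("EV005", 3.0),),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_design_cohort():
    """The emulated study design: 6 deficient donors, weekly sampling."""
    cfg = SimConfig(
        seed=13,
        n_deficient=6,
        n_sufficient=3,
        n_variables_invivo=3,
        n_variables_exvivo=3,
        planted_edges=(("IV001", "EV001", 0.97),),
        outlier_rate=0.0,
        nonnormal_fraction=0.0,
    )
    return generate_cohort(cfg)


def make_long_records():
    """2 variables x 3 donors x 2 timepoints, canonical long layout."""
    rows = []
    for di, donor in enumerate(["d1", "d2", "d3"]):
        rows.append(
            {"variable": "glucose_iv", "donor": donor, "group": "deficient",
             "timepoint": "NS", "compartment": "in_vivo",
             "value": 1.0 + di}
        )
        rows.append(
            {"variable": "lactate_ev", "donor": donor, "group": "deficient",
             "timepoint": "D7", "compartment": "ex_vivo",
             "value": 10.0 + di}
        )
    return rows


@pytest.fixture
def tiny_long_df():
    return pd.DataFrame(make_long_records())


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
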