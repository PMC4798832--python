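"""Shared fixtures: small simulated data sets built at session scope."""

import pandas as pd
import pytest

from ncii.design import make_design
from ncii.simulate import SimulationParams, TraitParams, simulate_phenotypes
import ncii


def balanced_allocation(n_dams=4, n_sires=12, reps=6, group="control"):
    """Single-group, perfectly balanced family x replicate allocation."""
    design = make_design(n_dams, n_sires)
    rows = [
        (s, d, group, group, r)
        for s, d in design.families
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(
        rows, columns=["sire_id", "dam_id", "raw_group", "analysis_group", "replicate"]
    )


def quiet_params(s2_s=0.25, s2_d=0.25, s2_sd=0.10, s2_e=0.40, mean=400.0, **kw):
    """One-trait simulation parameters: no mortality, no measurement subset."""
    return SimulationParams(
        hatch=TraitParams(
            mean=mean, s2_sire=s2_s, s2_dam=s2_d, s2_sire_dam=s2_sd, s2_resid=s2_e,
            treatment_effects=kw.pop("treatment_effects", {}),
            rho_g=kw.pop("rho_g", 1.0),
        ),
        p_mort=0.0,
        measure_fraction=0.0,
        **kw,
    )


@pytest.fixture(scope="session")
def balanced_records():
    """Balanced 4 x 12 x 6 NC II table at (0.25, 0.25, 0.10, 0.40)."""
    return simulate_phenotypes(balanced_allocation(), quiet_params(), seed=101)


@pytest.fixture(scope="session")
def study_records():
    """Full study-scale simulation: 48 families, 9 raw groups, 5-7 reps."""
    return ncii.simulate_dataset(seed=202)


@pytest.fixture(scope="session")
def two_group_records(study_records):
    return study_records[
        study_records["analysis_group"].isin(["control", "agno3_high"])
    ].reset_index(drop=True)
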