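import numpy as np
import pandas as pd
import pytest

from ctflow.pipeline import analyze_cohort
from ctflow.simulate import SimulationConfig, simulate_cohort
from ctflow.types import CtMatrix, SampleSheet


def make_ct(values, assays=None, samples=None, detected=None, stage="raw"):
    """Build a CtMatrix from a 2-d array-like (assays x samples)."""
    values = np.asarray(values, dtype=float)
    assays = assays or [f"A{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    if detected is None:
        detected = np.isfinite(values)
    return CtMatrix(
        pd.DataFrame(values, index=assays, columns=samples),
        pd.DataFrame(np.asarray(detected, dtype=bool), index=assays, columns=samples),
        stage=stage,
    )


def make_sheet(patients, controls, **extra_columns):
    """Minimal sample sheet with the given patient/control sample ids."""
    index = list(patients) + list(controls)
    df = pd.DataFrame(
        {"cohort": ["patient"] * len(patients) + ["control"] * len(controls)},
        index=pd.Index(index, name="sample_id"),
    )
    flags = []
    for name, values in extra_columns.items():
        df[name] = values
        if set(pd.Series(values).dropna().unique()) <= {0, 1}:
            flags.append(name)
    return SampleSheet(df, flags=flags)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size cohort config for fast multi-seed experiments."""
    return SimulationConfig(n_assays=60, n_de_assays=6, n_reference_like=12,
                            n_subgroup_markers=2)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort (paper-shaped)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    ct, sheet, panel, truth = default_cohort
    return analyze_cohort(ct, sheet, panel), truth
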