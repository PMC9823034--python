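import numpy as np
import pandas as pd
import pytest

from squidms import InjectionSchedule, SimulationConfig, simulate_run


def make_agmatine_targets() -> pd.DataFrame:
    """Light/heavy agmatine target table with theoretical [M+H]+ m/z values."""
    return pd.DataFrame(
        {
            "name": ["agmatine", "[U-13C]agmatine"],
            "formula": ["C5H14N4", "C5H14N4"],
            "n_labeled_13C": [0, 5],
            "role": ["analyte", "internal_standard"],
            "pair_id": ["agm", "agm"],
            "is_concentration_nM": [np.nan, 250.0],
            "mz": [131.129122, 136.145897],
        }
    )


@pytest.fixture(scope="session")
def agmatine_targets() -> pd.DataFrame:
    return make_agmatine_targets()


@pytest.fixture(scope="session")
def replicate_run():
    """12 technical-replicate injections, suppressed but noise-free, plus schedule."""
    config = SimulationConfig(
        n_injections=12, suppression_sigma=0.10, baseline_noise_sd=0.0, seed=3
    )
    run, truth = simulate_run(config)
    schedule = InjectionSchedule(
        t0=config.t0, cadence=config.cadence, n_injections=config.n_injections
    )
    return run, truth, schedule, config
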