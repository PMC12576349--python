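import numpy as np
import pandas as pd
import pytest

from cserisk import (
    PovertyGuideline,
    RunConfig,
    cohort_preset,
    compute_profiles,
    generate_tables,
)


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """One shared cohort-preset pipeline run at n=5000 households."""
    from cserisk import run_pipeline

    cfg = RunConfig(
        generator=cohort_preset(n_blockgroups=150, n_households=5000),
        outdir=str(tmp_path_factory.mktemp("cohort") / "run"),
        seed=20240101,
    )
    return run_pipeline(cfg)


@pytest.fixture()
def toy_profiles():
    """Three households with known NSE values."""
    return pd.DataFrame(
        {
            "hh_id": ["a", "b", "c"],
            "bg_id": ["g"] * 3,
            "size": [1, 2, 3],
            "insured": [False, False, True],
            "income_annual": [15000.0, 28000.0, 60000.0],
            "subsistence_annual": [5000.0, 8000.0, 10000.0],
            "nse": [10000.0, 20000.0, 50000.0],
            "below_poverty": [True, False, False],
        }
    )


def make_profiles_from_nse(nse):
    """Wrap raw NSE values in a minimal profile frame."""
    nse = np.asarray(nse, dtype=float)
    return pd.DataFrame(
        {
            "hh_id": [f"h{i}" for i in range(len(nse))],
            "bg_id": ["g"] * len(nse),
            "size": 2,
            "insured": False,
            "income_annual": nse + 1000.0,
            "subsistence_annual": 1000.0,
            "nse": nse,
            "below_poverty": False,
        }
    )
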