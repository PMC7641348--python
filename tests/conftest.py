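import numpy as np
import pandas as pd
import pytest

from heatscreen.synthetic_data import (SyntheticConfig, default_keyword_rules,
                                       generate_interventions, generate_tracts)
from heatscreen.vulnerability import assess_vulnerability, filter_complete_tracts


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_tracts=400, n_projects=250, seed=7)


@pytest.fixture(scope="session")
def tracts(small_config):
    return generate_tracts(small_config)


@pytest.fixture(scope="session")
def complete_tracts(tracts):
    return filter_complete_tracts(tracts)


@pytest.fixture(scope="session")
def assessments(complete_tracts):
    return assess_vulnerability(complete_tracts)


@pytest.fixture(scope="session")
def classified_interventions(small_config, complete_tracts):
    from heatscreen.interventions import dedupe_tract_interventions, keyword_screen
    raw = generate_interventions(small_config, complete_tracts)
    deduped = dedupe_tract_interventions(raw)
    return keyword_screen(deduped, default_keyword_rules(small_config))


def make_daily_series(tract_id="06000000001", model_id="CanESM2", years=(2006,),
                      tmax=30.0, tmin=None, rh=30.0):
    """One flat seasonal series per year, Apr 1 - Oct 31."""
    frames = []
    for y in years:
        dates = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
        n = len(dates)
        frames.append(pd.DataFrame({
            "tract_id": tract_id,
            "model_id": model_id,
            "scenario": "RCP4.5",
            "date": dates,
            "tmax_c": np.full(n, tmax, dtype=float),
            "tmin_c": np.full(n, tmax - 12.0 if tmin is None else tmin, dtype=float),
            "rhmin_pct": np.full(n, rh, dtype=float),
        }))
    return pd.concat(frames, ignore_index=True)
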