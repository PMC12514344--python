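"""Shared fixtures: synthetic sites and their pipeline products.

Everything is generated programmatically and cached per session so the
RF-heavy stages run once.
"""

import numpy as np
import pandas as pd
import pytest

import fluxlegacy as fl

#: ensemble size for test runs; estimates stabilize well below the
#: production default and the suite stays fast
N_TREES = 100


@pytest.fixture(scope="session")
def drought_site():
    """12-year site with one imposed drought and a 1-season −15% legacy."""
    cfg = fl.SyntheticConfig(
        seed=1,
        droughts=[fl.DroughtSpec(start_doy=150)],
        legacy=fl.LegacySpec(magnitude=-0.15, duration_seasons=1),
    )
    return fl.generate_site(cfg)


@pytest.fixture(scope="session")
def drought_anoms(drought_site):
    series, _ = drought_site
    rc = fl.RunConfig(n_trees=N_TREES, seed=1)
    return fl.prepare_anomalies(series, rc)


@pytest.fixture(scope="session")
def drought_events(drought_anoms):
    rc = fl.RunConfig(n_trees=N_TREES, seed=1)
    events, sigma = fl.detect_droughts(drought_anoms, rc)
    return events, sigma


@pytest.fixture(scope="session")
def quiet_site():
    """8-year site without imposed droughts."""
    cfg = fl.SyntheticConfig(seed=7, years=8, site_id="SYN-QUIET")
    return fl.generate_site(cfg)


@pytest.fixture()
def daily_index():
    def make(years=10, start=2000):
        return pd.date_range(f"{start}-01-01", f"{start + years - 1}-12-31", freq="D")
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
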