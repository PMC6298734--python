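import numpy as np
import pandas as pd
import pytest

import nichepart as nip


@pytest.fixture(scope="session")
def small_scenario():
    return nip.default_scenario(
        seed=7, years=(1993, 1999, 2005, 2011), hauls_per_year=300
    )


@pytest.fixture(scope="session")
def survey_tables(small_scenario):
    hauls, truth = nip.simulate_hauls(small_scenario)
    specimens = nip.simulate_lengths(hauls, small_scenario)
    stomachs = nip.simulate_stomachs(
        hauls, specimens, nip.default_diet_scenario(seed=7)
    )
    return dict(hauls=hauls, truth=truth, specimens=specimens,
                stomachs=stomachs)


@pytest.fixture(scope="session")
def ingested(survey_tables):
    retained, report = nip.filter_complete_covariates(survey_tables["hauls"])
    retained = retained.copy()
    for sp in ("PH", "ATF"):
        retained[f"adjusted_cpue_{sp}"] = nip.adjusted_cpue(
            retained, survey_tables["specimens"], sp
        )
    return dict(hauls=retained, report=report)


@pytest.fixture(scope="session")
def goa_grid(survey_tables):
    h = survey_tables["hauls"]
    extent = (float(h["lon"].min()), float(h["lon"].max()),
              float(h["lat"].min()), float(h["lat"].max()))
    return nip.build_grid(extent)


def random_composition(rng, q):
    """Random strict composition over q taxa (helper for formula oracles)."""
    w = rng.dirichlet(np.ones(q) * rng.uniform(0.3, 3.0))
    return pd.Series(w, index=[f"taxon_{i}" for i in range(q)])
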