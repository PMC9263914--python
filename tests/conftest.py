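import datetime as dt

import numpy as np
import pytest

from isopart.mixing import MCMCConfig, MixtureObservation, SourceLayer
from isopart.isotopes import SampleKind, WaterSample


@pytest.fixture
def well_separated_sources():
    """Four layer sources well separated in both isotopes (sds 0.2 / 1.0)."""
    d18O = [-2.0, -6.0, -10.0, -14.0]
    dD = [-20.0, -50.0, -80.0, -110.0]
    bounds = [(0, 5), (5, 20), (20, 60), (60, 100)]
    return [
        SourceLayer(
            label=f"{t}-{b}cm", top_cm=t, bottom_cm=b,
            mean_d18O=m18, sd_d18O=0.2, mean_dD=mD, sd_dD=1.0, n=3,
        )
        for (t, b), m18, mD in zip(bounds, d18O, dD)
    ]


@pytest.fixture
def fast_mcmc():
    """Short chains for unit tests; acceptance tests use the defaults."""
    return MCMCConfig(n_chains=4, n_iter=6000, burn_in=2000, thin=4, seed=0)


def make_soil(depth_cm, d18O, dD=None, date=dt.date(2016, 7, 1), treatment="P1-N240"):
    return WaterSample(
        sample_id=f"s-{depth_cm}",
        kind=SampleKind.SOIL,
        date=date,
        treatment=treatment,
        depth_cm=depth_cm,
        d18O_permil=d18O,
        dD_permil=dD if dD is not None else 5.5 * d18O - 8.0,
    )


@pytest.fixture
def soil_factory():
    return make_soil
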