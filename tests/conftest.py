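import numpy as np
import pytest

import nadasekin as nk

# Reference fitted constants used as ground truths throughout the suite.
CD38_NAD = {"Km": 10.4, "Vmax": 6649.0}
SAMTIR_NAD = {"Km": 69.5, "Vmax": 723.0}
SAMTIR_NADP = {"Km": 83.5, "Vmax": 582.0, "Kis": 151.0}
FL_NAD = {"Km": 30.3, "Vmax": 22.4, "Kia": 324.0}
FL_NADP = {"Km": 66.9, "Vmax": 14.3, "Kis": 132.0}


@pytest.fixture(scope="session")
def cd38_params():
    return nk.MichaelisParameters(**CD38_NAD)


@pytest.fixture(scope="session")
def samtir_nadp_params():
    return nk.CatalyticInhibitionParameters(
        base=nk.MichaelisParameters(Km=83.5, Vmax=582.0), Kis=151.0
    )


@pytest.fixture(scope="session")
def fl_nad_params():
    return nk.DualInhibitionParameters(
        base=nk.CatalyticInhibitionParameters(
            base=nk.MichaelisParameters(Km=30.3, Vmax=22.4)
        ),
        Kia=324.0,
    )


def noiseless_dataset(model, params, **kw):
    cfg = nk.SimulationConfig(model=model, params=params, cv=0.0, seed=0, **kw)
    return nk.generate_initial_rates(cfg)


@pytest.fixture(scope="session")
def fl_nad_dataset():
    return noiseless_dataset("eq3", FL_NAD)


@pytest.fixture(scope="session")
def samtir_nadp_dataset():
    return noiseless_dataset("eq2", SAMTIR_NADP)


@pytest.fixture(scope="session")
def balanced_course():
    """Noiseless 90:10 hydrolysis:cyclization progress curve, mild consumption."""
    scheme = nk.BranchingScheme(
        model="eq3", params=FL_NAD, f_hydrolysis=0.9, f_cyclization=0.1,
        protein_conc=100.0,
    )
    tc, events = nk.simulate_time_course(scheme, S0=250.0, duration=30.0)
    assert not events
    return tc
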