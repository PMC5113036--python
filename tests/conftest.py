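import numpy as np
import pytest

import tipstalk as ts

VEGF_AXIS = np.linspace(0.0, 10.0, 21)


@pytest.fixture(scope="session")
def vegf_grid_spec():
    return ts.GridSpec(VEGF_AXIS, VEGF_AXIS, "V1xV2")


@pytest.fixture(scope="session")
def vegf_sweep(vegf_grid_spec):
    """Full default V1 x V2 sweep (shared: it is the priciest artifact)."""
    scenarios = ts.make_vegf_grid(vegf_grid_spec)
    return ts.sweep(scenarios, shape=vegf_grid_spec.shape)


@pytest.fixture(scope="session")
def vegf_sweep_prepatterned(vegf_grid_spec):
    """Same VEGF grid with the Dext = (0, 1) pre-patterning bolus added."""
    scenarios = [
        ts.ExternalInputs(V1=s.V1, V2=s.V2, Dext1=0.0, Dext2=1.0)
        for s in ts.make_vegf_grid(vegf_grid_spec)
    ]
    return ts.sweep(scenarios, shape=vegf_grid_spec.shape)


@pytest.fixture(scope="session")
def nominal_dext_branch():
    """Continuation of the pre-patterned A:I state along the overtaking path."""
    path = ts.DextPath()
    eqs = ts.find_equilibria(path.inputs_at(0.0), n_seeds=2)
    start = max((e for e in eqs if e.stable), key=lambda e: e.state[2])
    assert start.state[2] > ts.ACTIVE_DLL
    return path, ts.continue_branch(start, path)


@pytest.fixture(scope="session")
def branch_set():
    from tipstalk.classify import default_branches

    return default_branches()


@pytest.fixture(scope="session")
def profile_clustering(branch_set):
    profiles = ts.collect_profiles(branch_set, picks=[0.25, 0.5, 0.75])
    return profiles, ts.cluster_profiles(profiles, k=4)


@pytest.fixture(scope="session")
def sirt1_scan():
    levels = list(np.geomspace(0.05, 12.0, 13))
    return ts.modulator_scan("sirt1", levels)
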