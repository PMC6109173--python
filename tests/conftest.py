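import numpy as np
import pytest

from epismoke import annotate as ann
from epismoke import peaks as pk
from epismoke.simulate import SimConfig, SimulatedData, simulate_all

#: fixed fixture seed for the default synthetic study
FIXTURE_SEED = 2018


@pytest.fixture(scope="session")
def sim_default() -> SimulatedData:
    """One default-condition synthetic study shared across the session."""
    return simulate_all(SimConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def classified_default(sim_default):
    """Classified + M-A-normalized peaks of the default study."""
    classified = pk.classify_peaks(sim_default.air_peaks, sim_default.smoke_peaks)
    pk.annotate_ma(classified)
    fit = pk.fit_ma_normalization([p for p in classified if p.label == "common"])
    pk.normalize_and_score(classified, fit)
    return classified, fit


@pytest.fixture(scope="session")
def assignments_default(sim_default, classified_default):
    classified, _ = classified_default
    return ann.assign_nearest_tss(classified, sim_default.annotation)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(FIXTURE_SEED)
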