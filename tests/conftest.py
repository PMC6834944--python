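import numpy as np
import pytest

from navmex.defaults import initial_guess
from navmex.params import ConstructParameters, load_construct


@pytest.fixture(scope="session")
def wt_initial():
    """Uncalibrated but valid WT parameter set (fast to build)."""
    return initial_guess("WT")


def _load_or_initial(name: str) -> ConstructParameters:
    try:
        return load_construct(name)
    except FileNotFoundError:
        return initial_guess(name)


@pytest.fixture(scope="session")
def wt():
    return _load_or_initial("WT")


@pytest.fixture(scope="session")
def rp():
    return _load_or_initial("R1626P")


@pytest.fixture(scope="session")
def mr():
    return _load_or_initial("M1652R")


@pytest.fixture(scope="session")
def boosted():
    try:
        return load_construct("M1652R_boosted")
    except FileNotFoundError:
        pytest.skip("no shipped booster parameters")


@pytest.fixture(scope="session")
def all_constructs(wt, rp, mr):
    return {"WT": wt, "R1626P": rp, "M1652R": mr}
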