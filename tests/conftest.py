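import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from c4iso.forcing import ForcingSpec, make_forcing
from c4iso.pipeline import RunConfig, run_land

SEED = 1234


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig(seed=SEED)


@pytest.fixture(scope="session")
def forcing(run_cfg):
    return make_forcing(ForcingSpec(seed=SEED))


@pytest.fixture(scope="session")
def land(forcing, run_cfg):
    """(cellflux, fractions, annual series) for the default synthetic domain."""
    return run_land(forcing, run_cfg)
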