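import numpy as np
import pytest

from rtmfa import (
    ChemostatConfig,
    SpectraConfig,
    load_pichia_network,
    simulate_chemostat,
    spectra_for_simulation,
)
from rtmfa import nirs
from rtmfa.network import load_network

STATES = (("A", 0.05), ("B", 0.10), ("C", 0.15))

TOY_NETWORK = """\
metabolite GLYext "glycerol (medium)" extracellular unbalanced
metabolite GAP "glyceraldehyde-3-phosphate" cytosol balanced
metabolite PYR "pyruvate" cytosol balanced
metabolite PYRext "pyruvate (medium)" extracellular unbalanced
r1: GLYext -> GAP measured
r2: GAP -> PYR
r3: PYR -> PYRext measured
"""

# one balanced pool fed by a measured influx, drained by a measured and an
# unknown efflux: the smallest exactly-determined balancing problem
TOY_POOL = """\
metabolite Ain "feed" extracellular unbalanced
metabolite B "pool" cytosol balanced
metabolite Aout "drain" extracellular unbalanced
r1: Ain -> B measured
r2: B -> Aout measured
r3: B -> Aout
"""

# both fluxes of a single pool measured: one redundant equation
TOY_REDUNDANT = """\
metabolite Ain "feed" extracellular unbalanced
metabolite B "pool" cytosol balanced
metabolite Aout "drain" extracellular unbalanced
r1: Ain -> B measured
r2: B -> Aout measured
"""


def _write_network(tmp_path_factory, text, name):
    path = tmp_path_factory.mktemp("networks") / name
    path.write_text(text)
    return load_network(path)


@pytest.fixture(scope="session")
def pichia():
    return load_pichia_network()


@pytest.fixture(scope="session")
def toy_model(tmp_path_factory):
    return _write_network(tmp_path_factory, TOY_NETWORK, "toy.txt")


@pytest.fixture(scope="session")
def pool_model(tmp_path_factory):
    return _write_network(tmp_path_factory, TOY_POOL, "pool.txt")


@pytest.fixture(scope="session")
def redundant_model(tmp_path_factory):
    return _write_network(tmp_path_factory, TOY_REDUNDANT, "redundant.txt")


@pytest.fixture(scope="session")
def sim():
    """Default noisy chemostat simulation, seed-pinned."""
    return simulate_chemostat(ChemostatConfig(seed=3))


@pytest.fixture(scope="session")
def sim_noiseless():
    return simulate_chemostat(ChemostatConfig(seed=0, sd_X=0.0, sd_S=0.0,
                                              gas_rel_sd=0.0))


@pytest.fixture(scope="session")
def spectra(sim):
    return spectra_for_simulation(sim, SpectraConfig(seed=4))


@pytest.fixture(scope="session")
def calibrations(sim, spectra):
    """PLS models for both analytes trained on the noisy off-line record."""
    series = sim.series
    with np.errstate(all="ignore"):
        return {
            "biomass": nirs.calibrate(
                spectra, series.time, series.X, "biomass", (1250, 1350), 5,
                n_val=30, seed=7,
            ),
            "glycerol": nirs.calibrate(
                spectra, series.time, series.S, "glycerol", (1500, 1800), 3,
                n_val=30, seed=7,
            ),
        }
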