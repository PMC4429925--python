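"""Shared fixtures: small simulated datasets and fitted chains.

Fits are deliberately small (a tenth of the emulated study, short chains) so
the whole suite runs in minutes; the statistical assertions account for the
resulting Monte-Carlo error.
"""

import warnings

import numpy as np
import pytest

import sirsem as ss


@pytest.fixture(scope="session")
def m2_truth():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ss.default_truth("M2")


@pytest.fixture(scope="session")
def m3_truth():
    return ss.default_truth("M3")


@pytest.fixture(scope="session")
def m2_sim(m2_truth):
    design = ss.default_design(seed=11, scale=0.1)
    return ss.simulate(design, m2_truth, seed=12)


@pytest.fixture(scope="session")
def chain_config():
    return ss.ChainConfig(n_iter=1500, burn_in=500, thin=2, seed=7)


@pytest.fixture(scope="session")
def m2_chain(m2_sim, chain_config):
    structure = ss.preset_structure("M2")
    return ss.run_chain(
        m2_sim.records, structure, m2_sim.design.pedigree, config=chain_config
    )


@pytest.fixture(scope="session")
def m0_chain(m2_sim, chain_config):
    structure = ss.preset_structure("M0")
    return ss.run_chain(
        m2_sim.records, structure, m2_sim.design.pedigree, config=chain_config
    )


@pytest.fixture(scope="session")
def tiny_sim(m2_truth):
    design = ss.default_design(seed=21, scale=0.02)
    return ss.simulate(design, m2_truth, seed=22)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
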