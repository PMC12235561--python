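"""Shared fixtures: simulated acquisitions and reconstructions reused across tests.

Expensive pipeline runs (full joint reconstructions) are session-scoped so
each study condition is simulated and reconstructed once.
"""

import warnings

import numpy as np
import pytest

from msdwi import (
    JointReconstruction,
    LLRConfig,
    SimulationConfig,
    protocol1_analog,
    protocol2_analog,
    retrospective_undersample,
    sigma_for_snr,
    simulate_acquisition,
)

SEED = 0


@pytest.fixture(scope="session")
def p1_noiseless():
    """Noiseless four-shot fully sampled (union) navigator-based acquisition."""
    cfg = SimulationConfig(protocol=protocol1_analog(), n_coils=8, noise_sigma=0.0, seed=SEED)
    return simulate_acquisition(cfg)


@pytest.fixture(scope="session")
def p1_recon_known_phases(p1_noiseless):
    """Inverse-crime reconstruction: true shot phases, no LLR penalty."""
    cfg = LLRConfig(lam=0.0)
    return JointReconstruction(p1_noiseless, cfg, phases=p1_noiseless.truth["phases"]).fit()


@pytest.fixture(scope="session")
def p1_recon_estimated_phases(p1_noiseless):
    """Full three-step pipeline at the default configuration (K=5)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return JointReconstruction(p1_noiseless, LLRConfig()).fit()


@pytest.fixture(scope="session")
def kyshift_reconstructions(p1_noiseless):
    """Retrospective one-shot-per-encoding reconstructions for the shift study."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for shift in (False, True):
            red = retrospective_undersample(p1_noiseless, 1, ky_shift=shift)
            out[("llr", shift)] = JointReconstruction(red, LLRConfig()).fit()
        red = retrospective_undersample(p1_noiseless, 1, ky_shift=True)
        out[("pi", True)] = JointReconstruction(red, LLRConfig(lam=0.0)).fit()
    return out


@pytest.fixture(scope="session")
def p2_snr20():
    """Three-shell MB=2 self-navigated acquisition at SNR ~ 20 plus its recon."""
    cfg = SimulationConfig(
        protocol=protocol2_analog(), n_coils=8, noise_sigma=sigma_for_snr(20.0), seed=SEED
    )
    data = simulate_acquisition(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = JointReconstruction(data, LLRConfig()).fit()
    return data, result
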