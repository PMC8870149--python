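"""Shared fixtures: the slow coupled runs reused across acceptance tests.

One run family is shared session-wide: a three-member anisotropy family
(A = 0, 25, 50) of heterogeneous-patient runs on the default coarse mesh
over the full 43-day course, with the isotropic member split at day 41 so
drug-parameter sweeps can branch off its grown state without re-running the
growth phase.
"""

import dataclasses

import pytest

from gliomech.config import SimulationConfig
from gliomech.pipeline import run_simulation


def trio_config(anisotropy: float, duration: float = 43.0) -> SimulationConfig:
    cfg = SimulationConfig()
    cfg.growth.dt = 1.0
    cfg.growth.anisotropy = anisotropy
    cfg.growth.duration = duration
    if duration < cfg.drug.t_readout:
        cfg.drug.t_injection = cfg.drug.t_readout = duration
    return cfg


def continue_with_drug(grown, **drug_overrides):
    """Extend the day-41 grown state through the drug window to day 43."""
    cfg = dataclasses.replace(grown.config)
    cfg.growth = dataclasses.replace(cfg.growth, duration=43.0)
    cfg.drug = dataclasses.replace(cfg.drug, t_injection=41.0, t_readout=43.0,
                                   **drug_overrides)
    return run_simulation(cfg, start_state=grown.final, mesh=grown.mesh)


@pytest.fixture(scope="session")
def grown_a0():
    """Isotropic heterogeneous-patient run grown to day 41 (no drug yet)."""
    return run_simulation(trio_config(0.0, duration=41.0))


@pytest.fixture(scope="session")
def run_a0(grown_a0):
    return continue_with_drug(grown_a0)


@pytest.fixture(scope="session")
def run_a25():
    return run_simulation(trio_config(25.0))


@pytest.fixture(scope="session")
def run_a50():
    return run_simulation(trio_config(50.0))
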