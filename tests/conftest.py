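import numpy as np
import pytest

from hydroshell.config import AnalysisConfig
from hydroshell.synth import (PlantedSite, auto_site_positions,
                              generate_condition_ensemble, generate_trajectory,
                              toy_protein)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def scaffold():
    return toy_protein()


@pytest.fixture(scope="session")
def small_scaffold():
    return toy_protein(n_copies_per_type=1)


@pytest.fixture(scope="session")
def clean_ensemble():
    """Five conditions, 20 all-condition sites (0.2 Å jitter), 7 lone waters
    per condition, no desolvation filler — the clean-recovery regime."""
    models, truth = generate_condition_ensemble(None, seed=11)
    for m in models.values():
        m.superposed = True
    return models, truth


@pytest.fixture(scope="session")
def site_trajectory(small_scaffold):
    """2000-frame toy trajectory with 12 planted sites plus 1 kg/L bulk."""
    return generate_trajectory(None, n_frames=2000, n_sites=12,
                               scaffold=small_scaffold, seed=21)


@pytest.fixture(scope="session")
def residence_trajectory(small_scaffold):
    """Sites-only trajectory (no bulk) with planted τ = 10 ps near a glutamate."""
    pos = auto_site_positions(small_scaffold, 1, residue_name="GLU")
    sites = [PlantedSite(position=pos[0], occupancy=0.8, tau_ps=10.0)]
    return generate_trajectory(None, n_frames=5000, sites=sites,
                               bulk_density=0.0, scaffold=small_scaffold, seed=22)
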