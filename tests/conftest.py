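"""Shared fixtures.

The two full-size plaque runs (r-mutant MP0 and LIN MP1 at f_tau = f_beta
= 5, table defaults, 400 min) are expensive relative to everything else,
so they are session-scoped and reused by the plaque, metrics and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from linphage.metrics import metrics_trajectory
from linphage.plaque import PlaqueParams, simulate_plaque
from linphage.wellmixed import WellMixedParams, competition_outcome

SAMPLE_10MIN = np.arange(0.0, 400.0 + 1e-9, 10.0)


@pytest.fixture(scope="session")
def mp0_result():
    """r-mutant plaque, table defaults, sampled every 10 min to 400 min."""
    return simulate_plaque(PlaqueParams.default("r_mutant"), sample_times=SAMPLE_10MIN)


@pytest.fixture(scope="session")
def mp1_result():
    """LIN-phage plaque at f_tau = f_beta = 5, table defaults."""
    return simulate_plaque(
        PlaqueParams.default("lin_phage", f_tau=5.0, f_beta=5.0),
        sample_times=SAMPLE_10MIN,
    )


@pytest.fixture(scope="session")
def mp0_metrics(mp0_result):
    return metrics_trajectory(mp0_result)


@pytest.fixture(scope="session")
def mp1_metrics(mp1_result):
    return metrics_trajectory(mp1_result)


@pytest.fixture(scope="session")
def competition_55():
    """Mixed-culture competition at f_tau = f_beta = 5, table defaults."""
    return competition_outcome(5.0, 5.0)


@pytest.fixture()
def default_params():
    return WellMixedParams()
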