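"""Shared fixtures: default network, growth trajectory, Spo0A~P map and
session-scoped stochastic ensembles reused across fate and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from sinswitch.deterministic import low_state
from sinswitch.growth import GrowthParams, simulate_growth
from sinswitch.network import build_sin_network, uM_to_counts
from sinswitch.spo0a import PhenomenologicalMap
from sinswitch.stochastic import simulate_ensemble

T_END = 14.0
SAMPLE_DT = 0.5
N_LINEAGES = 1000
N_LINEAGES_PERTURBED = 400


@pytest.fixture(scope="session")
def net():
    return build_sin_network()


@pytest.fixture(scope="session")
def growth_traj():
    return simulate_growth(GrowthParams(), 16.0)


@pytest.fixture(scope="session")
def slow_traj():
    return simulate_growth(GrowthParams().scaled_nutrient(), 16.0)


@pytest.fixture(scope="session")
def spo0a_map():
    return PhenomenologicalMap()


@pytest.fixture(scope="session")
def sample_times():
    return np.arange(0.0, T_END + 1e-9, SAMPLE_DT)


@pytest.fixture(scope="session")
def initial_counts(net, growth_traj, spo0a_map):
    """Matrix-off initial state per strain at the starting growth rate."""
    mu0 = growth_traj.mu[0]

    def _for(strain: str) -> np.ndarray:
        return np.round(uM_to_counts(
            low_state(net, mu0, float(spo0a_map(strain, mu0))))).astype(np.int64)

    return {s: _for(s) for s in ("WT", "dkinA", "dkinC", "dsda")}


@pytest.fixture(scope="session")
def ensembles(net, growth_traj, spo0a_map, sample_times, initial_counts):
    """Starvation-protocol ensembles for the four strains (fixed seeds)."""
    out = {}
    for strain in ("WT", "dkinA", "dkinC", "dsda"):
        out[strain] = simulate_ensemble(
            net, growth_traj, spo0a_map, strain, T_END, sample_times,
            initial_counts[strain], n_lineages=N_LINEAGES, seed=5)
    return out


@pytest.fixture(scope="session")
def slow_ensemble(net, slow_traj, spo0a_map, sample_times, initial_counts):
    """WT under the nutrient-reduced growth scenario, seed-matched to WT."""
    return simulate_ensemble(
        net, slow_traj, spo0a_map, "WT", T_END, sample_times,
        initial_counts["WT"], n_lineages=N_LINEAGES_PERTURBED, seed=5)


@pytest.fixture(scope="session")
def frozen_ensemble(net, growth_traj, spo0a_map, sample_times, initial_counts):
    """dkinC with the population growth rate held fixed from 6 h onward
    (the growth-arrest counterfactual; this strain's activation window is
    still open at the freeze time)."""
    return simulate_ensemble(
        net, growth_traj, spo0a_map, "dkinC", T_END, sample_times,
        initial_counts["dkinC"], n_lineages=N_LINEAGES_PERTURBED, seed=5,
        freeze_mu_after=6.0)
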