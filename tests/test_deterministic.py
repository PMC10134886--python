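"""Steady states, stability, bifurcation structure and hysteresis."""

import numpy as np
import pytest

from sinswitch.dosage import DEFAULT_LOCI
from sinswitch.network import (NetworkParams, Reaction, ReactionNetwork,
                               SPECIES, build_sin_network)
from sinswitch.deterministic import (REFERENCE_MU, find_steady_states,
                                     hysteresis_sweep, low_state,
                                     scan_bifurcation, sinr_slrr_ratio)


class TestFindSteadyStates:
    def test_birth_death_toy_unique_state(self):
        """Single-species production/loss has the unique stable state k/d."""
        k, d = 0.8, 0.4
        net = ReactionNetwork(species=SPECIES, reactions=(
            Reaction("tx_tapA", "tx", k, {"T": 1}, locus="tapA"),
            Reaction("deg_T", "uni", d, {"T": -1}, ("T",)),
        ), loci=dict(DEFAULT_LOCI), params=NetworkParams())
        mu = 0.3
        states = find_steady_states(net, mu=mu, spo0a=0.0, n_starts=3)
        stable = [s for s in states if s.stable]
        assert len(stable) == 1
        # transcription carries the cycle-averaged dosage factor; loss is
        # degradation plus dilution
        from sinswitch.dosage import average_copy_number
        dose = average_copy_number(net.loci["tapA"], mu)
        assert stable[0].tapa(net) == pytest.approx(k * dose / (d + mu),
                                                    rel=1e-6)

    def test_monostable_low_at_low_spo0a(self, net):
        states = find_steady_states(net, REFERENCE_MU, 0.05, n_starts=3)
        stable = [s for s in states if s.stable]
        assert len(stable) == 1
        assert stable[0].branch_label == "low"

    def test_bistable_at_high_spo0a(self, net):
        states = find_steady_states(net, REFERENCE_MU, 1.0, n_starts=3)
        stable = [s for s in states if s.stable]
        assert len(stable) == 2
        unstable = [s for s in states if not s.stable]
        assert len(unstable) == 1
        lo, hi = stable[0].tapa(net), stable[1].tapa(net)
        assert lo < unstable[0].tapa(net) < hi

    def test_invalid_start_count(self, net):
        with pytest.raises(ValueError):
            find_steady_states(net, 0.5, 0.5, n_starts=1)


class TestScanBifurcation:
    def test_deleting_slrr_transcription_removes_bistability(self):
        """Without the SinR-SlrR double-negative loop no grid cell is
        bistable (cross-checked by naive multi-start search)."""
        net = build_sin_network(NetworkParams(a_slrR=0.0))
        diag = scan_bifurcation(net, np.array([0.3, 0.6]),
                                np.array([0.3, 1.0, 2.0]), n_starts=4)
        assert np.all(diag.n_stable == 1)
        for mu in (0.3, 0.6):
            for s in (0.3, 2.0):
                stable = [x for x in find_steady_states(net, mu, s, n_starts=8)
                          if x.stable]
                assert len(stable) == 1

    def test_empty_grid_rejected(self, net):
        with pytest.raises(ValueError):
            scan_bifurcation(net, np.array([]), np.array([1.0]))


class TestSinrSlrrRatio:
    def _symmetric_params(self):
        # identical synthesis, turnover, loci; SlrR produced as dimer like
        # SinR2, heterotetramer decays symmetrically; no SinI (spo0a = 0)
        return NetworkParams(a_sinR=0.005, a_slrR=0.005, a_sinI=0.005,
                             k_deg_slrr=0.2, kon_LR=0.0, koff_LR=0.0)

    def test_symmetric_network_constant_ratio(self):
        from sinswitch.dosage import GeneLocus
        loci = {name: GeneLocus(name, 0.5) for name in DEFAULT_LOCI}
        net = build_sin_network(self._symmetric_params(), loci=loci)
        ratios = sinr_slrr_ratio(net, [0.15, 0.3, 0.5], spo0a=0.0)
        assert np.allclose(ratios, ratios[0], rtol=1e-4)

    def test_degradation_asymmetry_closed_form(self):
        """With binding off and equal loci the ratio follows the effective
        loss-rate quotient (0.6+mu)/(0.2+mu)."""
        from sinswitch.dosage import GeneLocus
        loci = {name: GeneLocus(name, 0.5) for name in DEFAULT_LOCI}
        p = NetworkParams(kon_LR=0.0, koff_LR=0.0)
        net = build_sin_network(p, loci=loci)
        mus = np.array([0.1, 0.25, 0.45, 0.6])
        ratios = sinr_slrr_ratio(net, mus, spo0a=0.0)
        expected = (0.6 + mus) / (0.2 + mus)
        norm = ratios / ratios[-1]
        norm_exp = expected / expected[-1]
        np.testing.assert_allclose(norm, norm_exp, rtol=0.02)

    def test_default_network_ratio_decreasing_in_mu(self, net):
        """The total SinR / total SlrR ratio rises as growth slows (the
        repressive arm of the incoherent feed-forward loop)."""
        mus = np.linspace(0.1, 0.6, 6)
        ratios = sinr_slrr_ratio(net, mus)
        assert np.all(np.diff(ratios) < 0)

    def test_gene_position_steepens_dependence(self):
        """Origin-proximal slrR vs terminus-proximal sinR adds a dosage
        factor that steepens the growth-rate dependence."""
        from sinswitch.dosage import GeneLocus, average_copy_number, c_period
        p = NetworkParams(kon_LR=0.0, koff_LR=0.0)
        same = {name: GeneLocus(name, 0.5) for name in DEFAULT_LOCI}
        net_same = build_sin_network(p, loci=same)
        net_real = build_sin_network(p)   # slrR near ori, sinR near ter
        mus = np.array([0.15, 0.3, 0.6])
        r_same = sinr_slrr_ratio(net_same, mus, spo0a=0.0)
        r_real = sinr_slrr_ratio(net_real, mus, spo0a=0.0)
        # normalized dosage quotient predicted by the copy-number model
        dose = np.array([
            average_copy_number(net_real.loci["sinR"], m)
            / average_copy_number(net_real.loci["slrR"], m) for m in mus])
        np.testing.assert_allclose((r_real / r_same) / (r_real[-1] / r_same[-1]),
                                   dose / dose[-1], rtol=0.03)


class TestHysteresis:
    def test_path_below_threshold_identical_traces(self, net):
        path = np.linspace(0.01, 0.05, 4)
        res = hysteresis_sweep(net, REFERENCE_MU, path, t_hold=60.0)
        np.testing.assert_allclose(res["tapa_up"], res["tapa_down"],
                                   rtol=1e-3, atol=1e-4)

    def test_window_matches_bifurcation_scan(self, net):
        """Up/down sweeps disagree exactly on the cells the two-parameter
        scan marks bistable (cross-validation of the two operations)."""
        spo0a_grid = np.array([0.05, 0.4, 1.2])
        res = hysteresis_sweep(net, REFERENCE_MU, spo0a_grid, t_hold=150.0)
        diag = scan_bifurcation(net, np.array([REFERENCE_MU]), spo0a_grid)
        disagree = np.abs(res["tapa_up"] - res["tapa_down"]) > 0.05 * (
            np.abs(res["tapa_down"]) + 1e-6)
        bistable = diag.n_stable[:, 0] == 2
        np.testing.assert_array_equal(disagree, bistable)

    def test_high_branch_retained_on_descent(self, net):
        """A lineage started high keeps expressing while Spo0A~P falls back
        through the bistable window (history dependence)."""
        path = np.array([0.05, 0.3, 0.8])
        res = hysteresis_sweep(net, REFERENCE_MU, path, t_hold=120.0)
        assert res["tapa_down"][1] > 10 * res["tapa_up"][1]
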