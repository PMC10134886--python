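"""Stochastic engine validation: exact stationary laws, a direct-method
oracle, division statistics, determinism, and the system-size limit."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from sinswitch.dosage import DEFAULT_LOCI
from sinswitch.growth import GenerationTimeSampler
from sinswitch.network import (MOLECULES_PER_UM, NetworkParams, Reaction,
                               ReactionNetwork, SPECIES, build_sin_network,
                               uM_to_counts)
from sinswitch.stochastic import (CompiledStochastic, StochasticCellState,
                                  divide, simulate_fixed_condition)


def toy_network(reactions) -> ReactionNetwork:
    """Wrap hand-picked reactions in the standard species/loci frame."""
    return ReactionNetwork(species=SPECIES, reactions=tuple(reactions),
                           loci=dict(DEFAULT_LOCI), params=NetworkParams())


def birth_death(k_counts: float, d: float) -> ReactionNetwork:
    return toy_network([
        Reaction("tx_tapA", "tx", k_counts / MOLECULES_PER_UM, {"T": 1},
                 locus="tapA"),
        Reaction("deg_T", "uni", d, {"T": -1}, ("T",)),
    ])


class TestBirthDeathStationaryLaw:
    def test_poisson_mean_and_variance(self):
        """Linear birth-death settles to Poisson(k/d): mean and variance
        agree within 3 standard errors over ~10^5 correlated samples."""
        net = birth_death(100.0, 5.0)
        rec = simulate_fixed_condition(net, mu=0.5, spo0a=0.0, t_end=2500.0,
                                       sample_dt=0.5, seed=11,
                                       with_division=False)
        T = rec.species_counts("T")[20:]
        lam = 20.0
        # autocorrelation time ~ 1/d = 0.2 h -> samples ~independent at 0.5 h
        se_mean = math.sqrt(lam / len(T))
        assert abs(T.mean() - lam) < 3 * se_mean
        se_var = lam * math.sqrt(2.0 / len(T))
        assert abs(T.var() - lam) < 4 * se_var


class DirectMethodSSA:
    """Reference direct-method (first-reaction-free) implementation used as
    the independent oracle for the next-reaction engine."""

    def __init__(self, propensities, nu, seed):
        self.propensities = propensities
        self.nu = nu
        self.rng = np.random.default_rng(seed)

    def run(self, x0, t_end, sample_dt):
        x = np.array(x0, dtype=np.int64)
        t = 0.0
        samples = []
        next_sample = 0.0
        while True:
            a = self.propensities(x)
            a0 = a.sum()
            tau = self.rng.exponential(1.0 / a0) if a0 > 0 else np.inf
            while next_sample <= t + tau and next_sample <= t_end:
                samples.append(x.copy())
                next_sample += sample_dt
            if t + tau > t_end:
                return np.array(samples)
            t += tau
            j = self.rng.choice(len(a), p=a / a0)
            x += self.nu[j]


class TestNextReactionVersusDirectMethod:
    def test_stationary_histograms_agree(self):
        """NRM and a direct-method oracle produce the same stationary
        distribution for a 3-reaction nonlinear network (chi-square)."""
        k, d1, d2 = 120.0, 2.0, 0.05   # birth, linear decay, pair annihilation
        # rate constants are given in concentration units: the engine's
        # count-space propensities are k (zeroth), d1*n, d2*n*(n-1)
        net = toy_network([
            Reaction("tx_tapA", "tx", k / MOLECULES_PER_UM, {"T": 1},
                     locus="tapA"),
            Reaction("deg_T", "uni", d1, {"T": -1}, ("T",)),
            Reaction("ann_T", "homo", d2 * MOLECULES_PER_UM, {"T": -2}, ("T",)),
        ])
        rec = simulate_fixed_condition(net, mu=0.5, spo0a=0.0, t_end=4000.0,
                                       sample_dt=0.5, seed=3,
                                       with_division=False)
        nrm = rec.species_counts("T")[20:]

        iT = SPECIES.index("T")
        nu = np.zeros((3, len(SPECIES)), dtype=np.int64)
        nu[0, iT], nu[1, iT], nu[2, iT] = 1, -1, -2

        def props(x):
            n = x[iT]
            return np.array([k, d1 * n, d2 * n * (n - 1)])

        direct = DirectMethodSSA(props, nu, seed=4).run(
            np.zeros(len(SPECIES), dtype=np.int64), 4000.0, 0.5)[20:, iT]

        edges = np.arange(nrm.min() - 0.5, nrm.max() + 1.5, 2.0)
        h1, _ = np.histogram(nrm, bins=edges)
        h2, _ = np.histogram(direct, bins=edges)
        keep = (h1 + h2) > 10
        # scale to equal totals, two-sample chi-square
        n1, n2 = h1[keep].sum(), h2[keep].sum()
        chi2 = np.sum((h1[keep] * np.sqrt(n2 / n1)
                       - h2[keep] * np.sqrt(n1 / n2)) ** 2
                      / (h1[keep] + h2[keep]))
        dof = keep.sum() - 1
        assert chi2 < stats.chi2.ppf(0.999, dof)
        assert abs(nrm.mean() - direct.mean()) / direct.mean() < 0.03


class TestDivision:
    def test_zero_parent_stays_zero(self):
        state = StochasticCellState(
            counts=np.zeros(3, dtype=np.int64),
            gene_copies=np.ones(2, dtype=np.int64),
            cycle_start=0.0, tau_cyc=1.0, mu_cycle=0.5, spo0a_cycle=0.1)
        d = divide(state, np.random.default_rng(0))
        assert np.all(d.counts == 0)

    def test_daughters_conserve_parent(self):
        rng = np.random.default_rng(1)
        state = StochasticCellState(
            counts=rng.integers(0, 500, 8).astype(np.int64),
            gene_copies=np.full(2, 2, dtype=np.int64),
            cycle_start=0.0, tau_cyc=1.0, mu_cycle=0.5, spo0a_cycle=0.1)
        kept, other = divide(state, rng, keep_other=True)
        np.testing.assert_array_equal(kept.counts + other.counts, state.counts)
        assert np.all(kept.gene_copies == 1)

    def test_binomial_moments(self):
        """Kept-daughter counts over many divisions of a 100-molecule parent
        follow Binomial(100, 1/2)."""
        rng = np.random.default_rng(2)
        n_div = 10_000
        parent = StochasticCellState(
            counts=np.array([100], dtype=np.int64),
            gene_copies=np.ones(1, dtype=np.int64),
            cycle_start=0.0, tau_cyc=1.0, mu_cycle=0.5, spo0a_cycle=0.1)
        kept = np.array([divide(parent, rng).counts[0] for _ in range(n_div)])
        se = 5.0 / math.sqrt(n_div)
        assert abs(kept.mean() - 50.0) < 3 * se
        assert kept.var() == pytest.approx(25.0, rel=0.1)


class TestFullNetworkStochastic:
    def test_deterministic_under_fixed_seed(self, net):
        cs = CompiledStochastic(net)
        x0 = np.round(uM_to_counts(np.full(net.n_species, 0.02))).astype(np.int64)
        a = simulate_fixed_condition(cs, 0.5, 0.5, 10.0, 0.5, seed=42, x0=x0)
        b = simulate_fixed_condition(cs, 0.5, 0.5, 10.0, 0.5, seed=42, x0=x0)
        np.testing.assert_array_equal(a.counts_at, b.counts_at)
        assert a.events == b.events

    def test_no_negative_counts_and_replication_logged(self, net):
        rec = simulate_fixed_condition(net, 0.4, 1.0, 30.0, 0.25, seed=9)
        assert rec.counts_at.min() >= 0
        kinds = {e[1] for e in rec.events}
        assert kinds == {"replication", "division"}
        # replication precedes the division that ends each cycle
        reps = [t for t, k, _ in rec.events if k == "replication"]
        assert len(reps) > 10

    def test_bistable_switching_at_high_spo0a_only(self, net, initial_counts):
        """Fixed-condition lineages activate the matrix state stochastically
        at 1 uM Spo0A~P but never from 0.05 uM (monostable regime)."""
        x0 = initial_counts["WT"]
        cs = CompiledStochastic(net)
        high = simulate_fixed_condition(cs, 0.5, 1.0, 120.0, 0.5, seed=2, x0=x0)
        low = simulate_fixed_condition(cs, 0.5, 0.05, 120.0, 0.5, seed=2, x0=x0)
        t_high = high.species_counts("T")
        assert (t_high > 500).any()          # stochastic activation
        assert (t_high <= 500).any()         # and it is not immediate
        assert np.all(low.species_counts("T") <= 500)

    def test_low_growth_loses_bimodality(self, net, initial_counts):
        """At slow growth the matrix-on state is unavailable even at high
        Spo0A~P: the long-run distribution stays unimodal low."""
        rec = simulate_fixed_condition(CompiledStochastic(net), 0.12, 2.0,
                                       120.0, 0.5, seed=6,
                                       x0=initial_counts["WT"])
        assert np.all(rec.species_counts("T") <= 500)

    def test_system_size_limit_matches_ode(self, net):
        """At 1000x volume (counts ~1e5-1e6) a division-free lineage tracks
        the reaction-only ODE within 5% (system-size expansion limit)."""
        cs = CompiledStochastic(net, volume_scale=1000.0)
        comp = net.compiled()
        mu, spo0a = 0.5, 0.3
        x0_uM = np.full(net.n_species, 0.05)
        x0 = np.round(x0_uM * cs.omega).astype(np.int64)
        recs = [simulate_fixed_condition(cs, mu, spo0a, 1.0, 0.25, seed=1,
                                         x0=x0, with_division=False)]
        rec = recs[0]

        dose = comp.dose_factors(mu)

        def rhs(t, y):
            # reaction fluxes only: no dilution, fixed single gene copies
            r = comp.rates(y, mu, spo0a)
            for j in range(len(r)):
                if comp.kind[j] == 0:
                    r[j] /= dose[comp.locus_idx[j]]
            return comp.nu_T @ r

        sol = solve_ivp(rhs, (0, 1.0), x0_uM, t_eval=rec.sample_times,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        for name in ("R2", "R4", "T"):
            i = net.species_index(name)
            ode = sol.y[i] * cs.omega
            ssa = np.mean([r.counts_at[:, i] for r in recs], axis=0)
            sel = ode > 200
            assert np.all(np.abs(ssa[sel] - ode[sel]) / ode[sel] < 0.05)

    def test_replication_doubles_transcription_propensity(self, net):
        """Gene doubling shows up as a factor-2 step in mRNA production:
        compare mRNA levels for a gene held at 1 vs 2 copies."""
        cs = CompiledStochastic(net)
        j = next(i for i, r in enumerate(net.reactions) if r.name == "tx_sinR")
        counts = np.zeros(net.n_species, dtype=np.int64)
        copies1 = np.ones(len(cs.locus_names), dtype=np.int64)
        copies2 = 2 * copies1
        from sinswitch.stochastic import _propensity
        a1 = _propensity(j, counts, copies1, cs.kind, cs.c_hat, cs.idx1,
                         cs.idx2, cs.reg, cs.Khat, cs.nh,
                         cs.tx_mod(0.0), cs.locus_idx)
        a2 = _propensity(j, counts, copies2, cs.kind, cs.c_hat, cs.idx1,
                         cs.idx2, cs.reg, cs.Khat, cs.nh,
                         cs.tx_mod(0.0), cs.locus_idx)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)


class TestLineageProtocol:
    def test_lineage_reproducible_and_annotated(self, net, growth_traj,
                                                spo0a_map, initial_counts):
        from sinswitch.stochastic import simulate_lineage
        times = np.arange(0.0, 6.01, 0.5)
        kw = dict(sampler=GenerationTimeSampler(), seed=77)
        a = simulate_lineage(net, growth_traj, spo0a_map, "WT", 6.0, times,
                             initial_counts["WT"], **kw)
        b = simulate_lineage(net, growth_traj, spo0a_map, "WT", 6.0, times,
                             initial_counts["WT"], **kw)
        np.testing.assert_array_equal(a.counts_at, b.counts_at)
        np.testing.assert_array_equal(a.mu_at, b.mu_at)
        # each sample's Spo0A~P is the map evaluated at the cycle growth rate
        np.testing.assert_allclose(
            a.spo0a_at, [spo0a_map("WT", m) for m in a.mu_at], rtol=1e-9)

    def test_trajectory_too_short_rejected(self, net, growth_traj, spo0a_map,
                                           initial_counts):
        from sinswitch.stochastic import simulate_lineage
        with pytest.raises(ValueError):
            simulate_lineage(net, growth_traj, spo0a_map, "WT", 99.0,
                             [0.0], initial_counts["WT"])
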