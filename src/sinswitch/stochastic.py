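"""Stochastic lineage simulation: next-reaction kinetics with explicit
replication-timed gene doubling, per-cycle growth-rate and Spo0A~P
resampling, and binomial partitioning at division.

The engine follows one cell of a lineage.  At the start of each cycle the
cycle duration tau_cyc is drawn from a truncated normal around the
time-shift-corrected population mean (CV 0.25, minimum 0.2 h); the cycle's
growth rate is mu = ln2/tau_cyc and its Spo0A~P level is looked up from the
growth-rate map and held constant for the cycle.  Gene copy numbers reset
to 1 at birth and double at p*tau_c(mu) after birth.  At division every
molecular species is split Binomial(n, 1/2) and one daughter is followed.

Within a cycle the chemistry runs by the next-reaction method: each
reaction carries a putative firing time; after a firing, dependent
reactions' putative times are rescaled by their old/new propensity ratio
(redrawn for the fired reaction).  At discontinuous parameter changes
(cycle start, replication, division) all putative times are redrawn.
Propensities of second-order reactions use the fixed 4 fL cell volume.

Two random streams are used per lineage: a NumPy generator for cycle
durations and division partitions, and the numba kernel's internal stream
for reaction timing; both derive from the lineage seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dosage import c_period
from .growth import (GenerationTimeSampler, GrowthTrajectory,
                     corrected_mean_generation_time, sample_generation_time)
from .network import MOLECULES_PER_UM, ReactionNetwork

__all__ = [
    "LineageRecord",
    "StochasticCellState",
    "simulate_fixed_condition",
    "simulate_lineage",
    "divide",
    "CompiledStochastic",
]

LN2 = math.log(2.0)


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _seed_stream(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _propensity(j, counts, copies, kind, c_hat, idx1, idx2, reg, Khat, nh,
                tx_mod, locus_idx):
    k = kind[j]
    if k == 0:  # transcription
        a = c_hat[j] * tx_mod[j] * copies[locus_idx[j]]
        r = reg[j]
        if r >= 0:
            y = float(counts[r])
            kh = Khat[j] ** nh[j]
            a *= kh / (y ** nh[j] + kh)
        return a
    elif k == 1:  # unimolecular
        return c_hat[j] * counts[idx1[j]]
    elif k == 2:  # bimolecular heterodimer
        return c_hat[j] * counts[idx1[j]] * counts[idx2[j]]
    else:  # homodimerization: c/omega * n*(n-1)
        n = counts[idx1[j]]
        return c_hat[j] * n * (n - 1)


@njit(cache=True)
def _run_segment(counts, copies, t0, t1, kind, c_hat, idx1, idx2, reg, Khat,
                 nh, tx_mod, locus_idx, nu, dep, sample_times, si0, out):
    """Next-reaction simulation on [t0, t1] with constant parameters.

    Records the pre-event state at every sample time s with t0 < s <= t1,
    starting at index ``si0`` of ``sample_times``; returns the next unused
    sample index.  ``dep[j]`` flags reactions whose propensity may change
    when reaction j fires.
    """
    R = kind.shape[0]
    a = np.empty(R)
    tau = np.empty(R)
    t = t0
    for j in range(R):
        a[j] = _propensity(j, counts, copies, kind, c_hat, idx1, idx2, reg,
                           Khat, nh, tx_mod, locus_idx)
        tau[j] = t + (-math.log(np.random.random()) / a[j]) if a[j] > 0 else np.inf
    si = si0
    n_samples = sample_times.shape[0]
    while True:
        jmin = 0
        tmin = tau[0]
        for j in range(1, R):
            if tau[j] < tmin:
                tmin = tau[j]
                jmin = j
        t_adv = tmin if tmin < t1 else t1
        while si < n_samples and sample_times[si] <= t_adv:
            if sample_times[si] > t0:
                out[si, :] = counts
                si += 1
            else:
                si += 1
        if tmin > t1:
            break
        # fire jmin
        for s in range(nu.shape[1]):
            counts[s] += nu[jmin, s]
            if counts[s] < 0:
                raise RuntimeError("negative molecule count in SSA")
        t = tmin
        for k in range(R):
            if not dep[jmin, k]:
                continue
            a_new = _propensity(k, counts, copies, kind, c_hat, idx1, idx2,
                                reg, Khat, nh, tx_mod, locus_idx)
            if k == jmin or not np.isfinite(tau[k]):
                tau[k] = t + (-math.log(np.random.random()) / a_new) \
                    if a_new > 0 else np.inf
            else:
                if a_new > 0:
                    tau[k] = t + (a[k] / a_new) * (tau[k] - t) \
                        if a[k] > 0 else t + (-math.log(np.random.random()) / a_new)
                else:
                    tau[k] = np.inf
            a[k] = a_new
    return si


# --------------------------------------------------------------------------
# compiled count-space network
# --------------------------------------------------------------------------

class CompiledStochastic:
    """Count-space arrays of a ReactionNetwork for the NRM kernel.

    ``volume_scale`` multiplies the molecules-per-uM conversion (system-size
    parameter for deterministic-limit checks).
    """

    def __init__(self, net: ReactionNetwork, volume_scale: float = 1.0):
        self.net = net
        comp = net.compiled()
        self.comp = comp
        omega = MOLECULES_PER_UM * volume_scale
        self.omega = omega
        R = len(comp.c)
        self.kind = comp.kind.copy()
        self.idx1, self.idx2 = comp.idx1.copy(), comp.idx2.copy()
        self.reg = np.where(comp.reg >= 0, comp.reg, -1).astype(np.int64)
        self.spo0a_reaction = comp.reg == -2
        self.Khat = comp.K * omega
        self.nh = comp.n_hill.copy()
        self.mode_act = comp.mode_act
        self.locus_idx = np.where(comp.locus_idx >= 0, comp.locus_idx, 0)
        self.locus_names = comp.locus_names
        self.locus_p = comp.locus_p
        self.nu = comp.nu.copy()
        self.c_hat = np.empty(R)
        for j in range(R):
            k = comp.kind[j]
            if k == 0:
                self.c_hat[j] = comp.c[j] * omega
            elif k == 1:
                self.c_hat[j] = comp.c[j]
            elif k == 2:
                self.c_hat[j] = comp.c[j] / omega
            else:
                self.c_hat[j] = comp.c[j] / omega  # propensity uses n(n-1)
        # dependency: k depends on j if j changes a species k reads
        reads = [set() for _ in range(R)]
        for k in range(R):
            if self.kind[k] == 0:
                if self.reg[k] >= 0:
                    reads[k].add(self.reg[k])
            else:
                reads[k].add(self.idx1[k])
                if self.idx2[k] >= 0:
                    reads[k].add(self.idx2[k])
        self.dep = np.zeros((R, R), dtype=np.bool_)
        for j in range(R):
            changed = set(np.nonzero(self.nu[j])[0])
            for k in range(R):
                self.dep[j, k] = (k == j) or bool(changed & reads[k])

    def tx_mod(self, spo0a: float) -> np.ndarray:
        """Per-reaction constant promoter factor for a cycle (Spo0A~P Hill)."""
        mod = np.ones(len(self.c_hat))
        for j in np.nonzero(self.spo0a_reaction)[0]:
            s, n, K = spo0a, self.nh[j], self.comp.K[j]
            mod[j] = s**n / (s**n + K**n) if s > 0 else 0.0
        return mod


# --------------------------------------------------------------------------
# records and cell state
# --------------------------------------------------------------------------

@dataclass
class StochasticCellState:
    counts: np.ndarray
    gene_copies: np.ndarray
    cycle_start: float
    tau_cyc: float
    mu_cycle: float
    spo0a_cycle: float
    pending_events: list = field(default_factory=list)


@dataclass(frozen=True)
class LineageRecord:
    sample_times: np.ndarray
    counts_at: np.ndarray           # (n_samples, n_species)
    mu_at: np.ndarray
    spo0a_at: np.ndarray
    events: list                    # (time, kind, detail)
    seed: int
    species: tuple[str, ...]

    def species_counts(self, name: str) -> np.ndarray:
        return self.counts_at[:, self.species.index(name)]


def divide(state: StochasticCellState, rng: np.random.Generator,
           keep_other: bool = False):
    """Binomial partition of every species at division; gene copies reset.

    Returns the followed daughter (and the discarded one if requested);
    the two daughters' counts sum exactly to the parent's.
    """
    kept = rng.binomial(state.counts, 0.5).astype(np.int64)
    other = state.counts - kept
    daughter = StochasticCellState(
        counts=kept, gene_copies=np.ones_like(state.gene_copies),
        cycle_start=state.cycle_start + state.tau_cyc, tau_cyc=np.nan,
        mu_cycle=np.nan, spo0a_cycle=np.nan)
    if keep_other:
        sibling = StochasticCellState(
            counts=other, gene_copies=np.ones_like(state.gene_copies),
            cycle_start=daughter.cycle_start, tau_cyc=np.nan,
            mu_cycle=np.nan, spo0a_cycle=np.nan)
        return daughter, sibling
    return daughter


# --------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------

def _simulate_cycles(cs: CompiledStochastic, x0: np.ndarray,
                     sample_times: np.ndarray, t_end: float,
                     next_cycle, rng: np.random.Generator, seed: int,
                     with_replication: bool = True,
                     with_division: bool = True):
    """Shared cycle loop.  ``next_cycle(t) -> (tau, mu, spo0a)``."""
    n_sp = len(cs.net.species)
    counts = x0.astype(np.int64).copy()
    n_loci = len(cs.locus_names)
    out = np.zeros((len(sample_times), n_sp), dtype=np.int64)
    mu_at = np.zeros(len(sample_times))
    spo0a_at = np.zeros(len(sample_times))
    events: list[tuple[float, str, float]] = []
    _seed_stream(seed % (2**31 - 1))

    si = 0
    # samples at t = 0 record the initial state
    while si < len(sample_times) and sample_times[si] <= 0.0:
        out[si] = counts
        si += 1
    si0_mu = 0
    t = 0.0
    while t < t_end - 1e-12:
        tau, mu_c, spo0a = next_cycle(t)
        copies = np.ones(n_loci, dtype=np.int64)
        tc = c_period(mu_c)
        t_div = t + tau
        reps = sorted((p * tc, i) for i, p in enumerate(cs.locus_p)
                      if p * tc < tau) if with_replication else []
        tx_mod = cs.tx_mod(spo0a)
        bounds = [t + r for r, _ in reps] + [min(t_div, t_end)]
        locus_order = [i for _, i in reps]
        seg_start = t
        for b, which in zip(bounds, locus_order + [None]):
            if b > seg_start:
                si = _run_segment(counts, copies, seg_start, b, cs.kind,
                                  cs.c_hat, cs.idx1, cs.idx2, cs.reg, cs.Khat,
                                  cs.nh, tx_mod, cs.locus_idx, cs.nu, cs.dep,
                                  sample_times, si, out)
                seg_start = b
            if which is not None and b <= t_end:
                copies[which] = 2
                events.append((b, "replication", which))
        # per-sample cycle annotations (same cutoff as the kernel's recording)
        while si0_mu < len(sample_times) and sample_times[si0_mu] <= min(t_div, t_end):
            mu_at[si0_mu] = mu_c
            spo0a_at[si0_mu] = spo0a
            si0_mu += 1
        if t_div <= t_end and with_division:
            counts = rng.binomial(counts, 0.5).astype(np.int64)
            events.append((t_div, "division", np.nan))
        t = t_div
        last_mu, last_spo0a = mu_c, spo0a
    # samples that float-rounded past t_end carry the final state
    while si < len(sample_times):
        out[si] = counts
        si += 1
    while si0_mu < len(sample_times):
        mu_at[si0_mu] = last_mu
        spo0a_at[si0_mu] = last_spo0a
        si0_mu += 1
    return LineageRecord(sample_times=sample_times, counts_at=out,
                         mu_at=mu_at, spo0a_at=spo0a_at, events=events,
                         seed=seed, species=tuple(cs.net.species))


def simulate_fixed_condition(net: ReactionNetwork | CompiledStochastic,
                             mu: float, spo0a: float, t_end: float,
                             sample_dt: float = 0.5, seed: int = 0,
                             x0: np.ndarray | None = None,
                             sampler: GenerationTimeSampler = GenerationTimeSampler(),
                             with_division: bool = True) -> LineageRecord:
    """Lineage at constant growth rate and Spo0A~P, sampled on an arithmetic
    grid of spacing ``sample_dt`` (long-run sampling protocol)."""
    if t_end < sample_dt:
        raise ValueError("t_end must be at least sample_dt")
    cs = net if isinstance(net, CompiledStochastic) else CompiledStochastic(net)
    rng = np.random.default_rng(seed)
    sample_times = np.arange(0.0, t_end + 1e-9, sample_dt)
    if x0 is None:
        x0 = np.zeros(len(cs.net.species), dtype=np.int64)

    if with_division:
        def next_cycle(t):
            tau = sample_generation_time(LN2 / mu, sampler, rng)
            return tau, LN2 / tau, spo0a
    else:
        def next_cycle(t):
            return t_end - t + 1.0, mu, spo0a

    return _simulate_cycles(cs, np.asarray(x0), sample_times, t_end,
                            next_cycle, rng, seed + 1,
                            with_replication=with_division,
                            with_division=with_division)


def simulate_lineage(net: ReactionNetwork | CompiledStochastic,
                     traj: GrowthTrajectory, spo0a_map, strain: str,
                     t_end: float, sample_times, x0: np.ndarray,
                     sampler: GenerationTimeSampler = GenerationTimeSampler(),
                     seed: int = 0,
                     freeze_mu_after: float | None = None) -> LineageRecord:
    """One lineage under time-varying growth (starvation protocol).

    Per cycle: draw tau_cyc around the corrected population mean at the
    cycle start, set mu = ln2/tau_cyc, look up Spo0A~P for the strain, run
    the chemistry with replication-timed gene doubling, partition at
    division and follow one daughter.  ``freeze_mu_after`` clamps the
    population mean growth rate to its value at that time (growth-arrest
    counterfactual).
    """
    sample_times = np.asarray(sample_times, float)
    if traj.t_end < t_end:
        raise ValueError("growth trajectory shorter than t_end")
    if sample_times.size and (sample_times.min() < 0 or sample_times.max() > t_end):
        raise ValueError("sample_times must lie within [0, t_end]")
    cs = net if isinstance(net, CompiledStochastic) else CompiledStochastic(net)
    rng = np.random.default_rng(seed)
    if freeze_mu_after is not None:
        # growth arrest: mu(t) held at its value at the freeze time, so the
        # time-shift correction also saturates there
        from dataclasses import replace as _replace
        mask = traj.times <= freeze_mu_after
        mu_frozen = np.where(mask, traj.mu, traj.mu_at(freeze_mu_after))
        traj = _replace(traj, mu=mu_frozen)

    def next_cycle(t):
        t_eff = min(t, traj.t_end)
        tau_bar = corrected_mean_generation_time(traj, t_eff, sampler.epsilon)
        tau = sample_generation_time(tau_bar, sampler, rng)
        mu_c = LN2 / tau
        return tau, mu_c, float(spo0a_map(strain, mu_c))

    return _simulate_cycles(cs, np.asarray(x0), sample_times, t_end,
                            next_cycle, rng, seed + 1)


def simulate_ensemble(net: ReactionNetwork, traj: GrowthTrajectory, spo0a_map,
                      strain: str, t_end: float, sample_times, x0,
                      n_lineages: int, seed: int,
                      sampler: GenerationTimeSampler = GenerationTimeSampler(),
                      freeze_mu_after: float | None = None) -> list[LineageRecord]:
    """Independent lineages with child seeds ``seed*100000 + 2*i`` (each
    lineage consumes two adjacent seeds for its two streams)."""
    cs = CompiledStochastic(net)
    return [
        simulate_lineage(cs, traj, spo0a_map, strain, t_end, sample_times,
                         x0, sampler=sampler, seed=(seed * 100000 + 2 * i) % (2**31 - 1),
                         freeze_mu_after=freeze_mu_after)
        for i in range(n_lineages)
    ]
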