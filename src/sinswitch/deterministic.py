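"""Deterministic ODE analysis of the switch: steady states, stability,
two-parameter bifurcation scans, hysteresis sweeps, and the regulation-free
SinR/SlrR ratio.

Steady states are located by relaxing the ODE from multiple initial corners
(all-low, high-SlrR, plus continuation seeds), polishing with a root finder
and classifying stability from the Jacobian eigenvalues.  In a bistable cell
the separating unstable state is found by bisection along the segment
between the two stable states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ReactionNetwork, uM_to_counts

__all__ = [
    "SteadyState",
    "BifurcationDiagram",
    "find_steady_states",
    "scan_bifurcation",
    "sinr_slrr_ratio",
    "hysteresis_sweep",
    "low_state",
]

#: default analysis growth rate for one-parameter (Spo0A~P) cuts
REFERENCE_MU = 0.6

RESIDUAL_TOL = 1e-9
CLUSTER_TOL = 1e-6
STABILITY_MARGIN = 1e-8


@dataclass(frozen=True)
class SteadyState:
    state: np.ndarray
    stable: bool
    branch_label: str  # "low" | "high" | "unstable"
    residual: float
    eigmax: float

    def tapa(self, net: ReactionNetwork) -> float:
        return float(self.state[net.species_index("T")])


@dataclass(frozen=True)
class BifurcationDiagram:
    mu_grid: np.ndarray
    spo0a_grid: np.ndarray
    n_stable: np.ndarray       # (n_spo0a, n_mu) int
    tapa_low: np.ndarray       # (n_spo0a, n_mu)
    tapa_high: np.ndarray      # NaN where monostable

    def bistable_mask(self) -> np.ndarray:
        return self.n_stable == 2


def _jacobian(comp, x, mu, spo0a, h=1e-7):
    n = len(x)
    J = np.empty((n, n))
    f0 = comp.rhs(x, mu, spo0a)
    for i in range(n):
        dx = max(abs(x[i]), 1.0) * h
        xp = x.copy()
        xp[i] += dx
        J[:, i] = (comp.rhs(xp, mu, spo0a) - f0) / dx
    return J


def _relax(comp, x0, mu, spo0a, t_max=2000.0):
    """Integrate until the state stops moving; return the endpoint."""
    f = lambda t, y: comp.rhs(y, mu, spo0a)
    x = np.asarray(x0, dtype=float)
    for span in (50.0, 200.0, t_max):
        sol = solve_ivp(f, (0.0, span), x, method="LSODA",
                        rtol=1e-9, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"relaxation failed at mu={mu}, spo0a={spo0a}: "
                               f"{sol.message}")
        x_new = np.clip(sol.y[:, -1], 0.0, None)
        rel_rate = np.linalg.norm(comp.rhs(x_new, mu, spo0a)) / (
            np.linalg.norm(x_new) + 1e-12)
        x = x_new
        if rel_rate < 1e-9:
            break
    return x


def _polish(comp, x, mu, spo0a):
    sol = root(lambda y: comp.rhs(y, mu, spo0a), x, method="hybr",
               options={"xtol": 1e-12})
    y = np.clip(sol.x, 0.0, None)
    res = np.linalg.norm(comp.rhs(y, mu, spo0a))
    if sol.success and res <= np.linalg.norm(comp.rhs(x, mu, spo0a)) + 1e-12:
        return y, res
    return x, float(np.linalg.norm(comp.rhs(x, mu, spo0a)))


def _default_starts(net: ReactionNetwork, n_starts: int, rng) -> list[np.ndarray]:
    n = net.n_species
    # vegetative corner (SinR present, antagonists absent) relaxes into the
    # matrix-off basin; the SlrR-loaded corner into the matrix-on basin.
    high_r = np.zeros(n)
    high_r[net.species_index("R2")] = 1.0
    high_r[net.species_index("R4")] = 2.0
    high_l2 = np.zeros(n)
    high_l2[net.species_index("L2")] = 5.0
    high_l2[net.species_index("T")] = 5.0
    starts = [high_r, high_l2, np.zeros(n)]
    while len(starts) < n_starts:
        starts.append(rng.uniform(0.0, 3.0, size=n))
    return starts[:n_starts]


def find_steady_states(net: ReactionNetwork, mu: float, spo0a: float,
                       n_starts: int = 6, seed: int = 0,
                       extra_starts: list[np.ndarray] | None = None
                       ) -> list[SteadyState]:
    """All steady states at fixed (mu, Spo0A~P): 1 or 2 stable states plus,
    when bistable, the separating unstable state."""
    if n_starts < 2:
        raise ValueError("need at least 2 starts (low and high corners)")
    if mu < 0 or spo0a < 0:
        raise ValueError("mu and spo0a must be nonnegative")
    comp = net.compiled()
    rng = np.random.default_rng(seed)
    starts = _default_starts(net, n_starts, rng) + list(extra_starts or [])

    endpoints = []
    for x0 in starts:
        x = _relax(comp, x0, mu, spo0a)
        x, res = _polish(comp, x, mu, spo0a)
        endpoints.append((x, res))

    # cluster by relative distance
    clusters: list[tuple[np.ndarray, float]] = []
    for x, res in endpoints:
        for y, _ in clusters:
            if np.linalg.norm(x - y) <= CLUSTER_TOL * (1 + np.linalg.norm(y)):
                break
        else:
            clusters.append((x, res))

    iT = net.species_index("T")
    states = []
    for x, res in clusters:
        lam = np.linalg.eigvals(_jacobian(comp, x, mu, spo0a))
        eigmax = float(np.max(lam.real))
        # modes with |Re| below the margin (e.g. dynamically inert species)
        # are neutral and do not count as instabilities
        states.append(SteadyState(state=x, stable=eigmax < STABILITY_MARGIN,
                                  branch_label="", residual=res, eigmax=eigmax))
    stable = sorted([s for s in states if s.stable], key=lambda s: s.state[iT])
    if not stable:
        raise RuntimeError(
            f"no stable steady state located at mu={mu}, spo0a={spo0a}; "
            f"worst residual {max(s.residual for s in states):.2e}")
    labeled = []
    if len(stable) == 1:
        labeled.append(_with_label(stable[0], "low"))
    elif len(stable) >= 2:
        labeled.append(_with_label(stable[0], "low"))
        labeled.append(_with_label(stable[-1], "high"))
        labeled.append(_separatrix(comp, net, stable[0], stable[-1], mu, spo0a))
    return labeled


def _with_label(s: SteadyState, label: str) -> SteadyState:
    return SteadyState(s.state, s.stable, label, s.residual, s.eigmax)


def _separatrix(comp, net, lo: SteadyState, hi: SteadyState, mu, spo0a,
                iters: int = 40) -> SteadyState:
    """Bisection along the lo-hi segment for the unstable intermediate."""
    a, b = 0.0, 1.0
    x_lo, x_hi = lo.state, hi.state
    iT = net.species_index("T")
    thresh = 0.5 * (x_lo[iT] + x_hi[iT])
    for _ in range(iters):
        m = 0.5 * (a + b)
        x = (1 - m) * x_lo + m * x_hi
        x_end = _relax(comp, x, mu, spo0a, t_max=500.0)
        if x_end[iT] < thresh:
            a = m
        else:
            b = m
    x_mid = (1 - 0.5 * (a + b)) * x_lo + 0.5 * (a + b) * x_hi
    x, res = _polish(comp, x_mid, mu, spo0a)
    # the root polish can slide off the saddle onto a stable attractor;
    # keep the basin-boundary point instead when that happens
    t_lo, t_hi = x_lo[iT], x_hi[iT]
    if not (min(t_lo, t_hi) + 1e-9 < x[iT] < max(t_lo, t_hi) - 1e-9) or (
            np.linalg.norm(x - x_lo) < 1e-3 * (1 + np.linalg.norm(x_lo))
            or np.linalg.norm(x - x_hi) < 1e-3 * (1 + np.linalg.norm(x_hi))):
        x, res = x_mid, float(np.linalg.norm(comp.rhs(x_mid, mu, spo0a)))
    lam = np.linalg.eigvals(_jacobian(comp, x, mu, spo0a))
    return SteadyState(state=x, stable=False, branch_label="unstable",
                       residual=res, eigmax=float(np.max(lam.real)))


def low_state(net: ReactionNetwork, mu: float, spo0a: float) -> np.ndarray:
    """Low-TapA stable steady state (uM); the default initial condition
    (a vegetatively growing, matrix-off cell)."""
    states = find_steady_states(net, mu, spo0a, n_starts=3)
    return states[0].state


def low_state_counts(net: ReactionNetwork, mu: float, spo0a: float) -> np.ndarray:
    return np.round(uM_to_counts(low_state(net, mu, spo0a))).astype(np.int64)


def scan_bifurcation(net: ReactionNetwork, mu_grid, spo0a_grid,
                     n_starts: int = 4) -> BifurcationDiagram:
    """Stable-state count on a (Spo0A~P x mu) grid with continuation seeding.

    Each cell reuses the stable endpoints of its left/lower neighbors as
    extra starts, on top of the standard corners.
    """
    mu_grid = np.asarray(mu_grid, float)
    spo0a_grid = np.asarray(spo0a_grid, float)
    if mu_grid.size == 0 or spo0a_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(np.diff(mu_grid) <= 0) or np.any(np.diff(spo0a_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    ns = np.zeros((len(spo0a_grid), len(mu_grid)), dtype=int)
    lowT = np.full(ns.shape, np.nan)
    highT = np.full(ns.shape, np.nan)
    prev_row: list[list[np.ndarray]] = [[] for _ in mu_grid]
    for i, s in enumerate(spo0a_grid):
        prev_cell: list[np.ndarray] = []
        for j, m in enumerate(mu_grid):
            extra = prev_cell + prev_row[j]
            try:
                states = find_steady_states(net, m, s, n_starts=n_starts,
                                            extra_starts=extra)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"bifurcation scan failed at mu={m}, spo0a={s}") from exc
            stable = [st for st in states if st.stable]
            ns[i, j] = len(stable)
            lowT[i, j] = stable[0].tapa(net)
            if len(stable) == 2:
                highT[i, j] = stable[1].tapa(net)
            prev_cell = [st.state for st in stable]
            prev_row[j] = prev_cell
    return BifurcationDiagram(mu_grid=mu_grid, spo0a_grid=spo0a_grid,
                              n_stable=ns, tapa_low=lowT, tapa_high=highT)


def sinr_slrr_ratio(net: ReactionNetwork, mu_grid, spo0a: float = 1.0
                    ) -> np.ndarray:
    """Steady-state total-SinR / total-SlrR with slrR repression disabled.

    Isolates the growth-rate dependence coming from gene dosage and from the
    different dilution sensitivity of the stable SinR versus the rapidly
    degraded SlrR.
    """
    free = net.without_slrr_regulation()
    out = []
    for mu in np.asarray(mu_grid, float):
        if mu <= 0:
            raise ValueError("mu grid must be positive")
        states = find_steady_states(free, mu, spo0a, n_starts=3)
        x = states[0].state
        slrr = free.total_slrr(x)
        if slrr <= 0:
            raise ZeroDivisionError(f"zero SlrR steady state at mu={mu}")
        out.append(free.total_sinr(x) / slrr)
    return np.asarray(out)


def hysteresis_sweep(net: ReactionNetwork, mu: float, spo0a_path,
                     t_hold: float = 80.0) -> dict[str, np.ndarray]:
    """Quasi-static up-then-down sweep of Spo0A~P at fixed growth rate.

    The ascending pass starts from the matrix-off state at the lowest
    level; the descending pass starts from the matrix-on state at the
    highest level when one exists there (a lineage with a history of high
    expression).  Disagreement between the passes marks the hysteretic
    (bistable) window.
    """
    comp = net.compiled()
    path = np.asarray(spo0a_path, float)
    iT = net.species_index("T")

    def sweep(values, x0):
        x = np.asarray(x0, float)
        taps = []
        for s in values:
            x = _relax(comp, x, mu, s, t_max=t_hold)
            taps.append(x[iT])
        return np.asarray(taps), x

    x_low = low_state(net, mu, float(path[0]))
    up, x_top = sweep(path, x_low)
    stable_top = [s for s in find_steady_states(net, mu, float(path[-1]),
                                                n_starts=3) if s.stable]
    if len(stable_top) > 1:
        x_top = stable_top[-1].state
    down, _ = sweep(path[::-1], x_top)
    return {"spo0a": path, "tapa_up": up, "tapa_down": down[::-1]}
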