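"""Moser-type batch growth dynamics and stochastic generation times.

Population growth follows a nutrient-explicit Moser model,

    dC/dt = C * ( a * k_g * N^h1 / (N^h1 + K1^h1) - k_d * N^h2 / (N^h2 + K2^h2) )
    dN/dt = -gamma * C * ( k_g * N^h1 / (N^h1 + K1^h1)
                           - psi * k_d * N^h2 / (N^h2 + K2^h2) )

with cell density ``C`` in OD units and nutrient ``N`` normalized so that
N(0) = 1.  The population-mean single-cell growth rate is the growth Hill
term alone,

    mu(t) = k_g * N(t)^h1 / (N(t)^h1 + K1^h1),

and single-cell generation times are normally distributed around the mean
cycle length with CV 0.25, truncated from below.  Because a cycle's duration
is drawn at its *start* while the target mean describes cycles *alive* at a
given time, the mean is evaluated at a shifted time
``tau_cyc(t) = ln2 / mu(t + eps*ln2/mu(t))``; the shift factor ``eps`` is
calibrated (0.65 by default) so that the ensemble of cycles alive at t
reproduces mu(t) under the default growth scenario.

Prose convention for the death half-saturation: the death/sporulation Hill
term uses its own constant K2 (set ``death_uses_k1=True`` to share K1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GrowthParams",
    "GrowthTrajectory",
    "GenerationTimeSampler",
    "simulate_growth",
    "mean_growth_rate",
    "corrected_mean_generation_time",
    "sample_generation_time",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the Moser growth/death model (rates in 1/h)."""

    k_g: float = 0.8
    k_d: float = 0.18
    K1: float = 0.65
    K2: float = 0.05
    h1: float = 2.0
    h2: float = 4.0
    gamma: float = 0.55
    psi: float = 0.3
    a: float = 1.0
    C0: float = 0.1
    N0: float = 1.0
    death_uses_k1: bool = False

    def __post_init__(self) -> None:
        for name in ("k_g", "K1", "K2", "gamma", "C0", "N0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_d < 0 or self.a <= 0:
            raise ValueError("k_d must be >= 0 and a > 0")
        if not (self.h1 >= 1 and self.h2 >= 1):
            raise ValueError("Hill coefficients h1, h2 must be >= 1")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")

    def scaled_nutrient(self, factor: float = 3.0) -> "GrowthParams":
        """Scenario with the usable nutrient stock reduced ``factor``-fold.

        N stays normalized to 1, so the reduction appears as a
        ``factor``-fold larger effective yield coefficient: the same biomass
        drains the normalized stock ``factor`` times faster, giving an
        unchanged initial growth rate but an earlier slowdown (the
        nitrogen-reduced-medium scenario).
        """
        return replace(self, gamma=self.gamma * factor)


def mean_growth_rate(params: GrowthParams, N: float | np.ndarray) -> float | np.ndarray:
    """Population-mean growth rate mu at nutrient level ``N``."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("nutrient level must be nonnegative")
    h1, K1 = params.h1, params.K1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(N > 0, params.k_g * N**h1 / (N**h1 + K1**h1), 0.0)
    return float(mu) if mu.ndim == 0 else mu


@dataclass(frozen=True)
class GrowthTrajectory:
    """Time course of cell density, nutrient and mean growth rate."""

    times: np.ndarray
    C: np.ndarray
    N: np.ndarray
    mu: np.ndarray
    params: GrowthParams = field(repr=False, default=None)

    def mu_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Interpolated mu(t); clamped to the grid ends."""
        t = np.clip(t, self.times[0], self.times[-1])
        out = np.interp(t, self.times, self.mu)
        return float(out) if np.ndim(out) == 0 else out

    @property
    def t_end(self) -> float:
        return float(self.times[-1])


def _rhs(t, y, p: GrowthParams):
    C, N = y
    N = max(N, 0.0)
    g = p.k_g * N**p.h1 / (N**p.h1 + p.K1**p.h1) if N > 0 else 0.0
    Kd = p.K1 if p.death_uses_k1 else p.K2
    d = p.k_d * N**p.h2 / (N**p.h2 + Kd**p.h2) if N > 0 else 0.0
    return [C * (p.a * g - d), -p.gamma * C * (g - p.psi * d)]


def simulate_growth(params: GrowthParams, t_end: float, dt: float = 0.01,
                    rtol: float = 1e-8, atol: float = 1e-10) -> GrowthTrajectory:
    """Integrate the growth model on a uniform grid of spacing ``dt``."""
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    sol = solve_ivp(_rhs, (0.0, float(times[-1])), [params.C0, params.N0],
                    t_eval=times, args=(params,), method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad = np.argmax(~np.all(np.isfinite(sol.y), axis=0)) if sol.success else -1
        t_bad = times[bad] if bad >= 0 else sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(f"growth integration failed near t={t_bad:.3f} h: "
                           f"{sol.message}")
    C = sol.y[0]
    N = np.clip(sol.y[1], 0.0, None)
    mu = np.asarray(mean_growth_rate(params, N))
    return GrowthTrajectory(times=times, C=C, N=N, mu=mu, params=params)


def corrected_mean_generation_time(traj: GrowthTrajectory, t: float,
                                   epsilon: float = 0.65) -> float:
    """Mean cycle length for a cycle *starting* at ``t``.

    Returns ln2 / mu(t + dt) with dt = epsilon * ln2 / mu(t); past the end of
    the trajectory grid mu is held at its final value.
    """
    if not traj.times[0] <= t <= traj.times[-1]:
        raise ValueError(f"t={t} outside trajectory range")
    mu_now = traj.mu_at(t)
    if mu_now <= 0:
        raise ZeroDivisionError(f"degenerate growth: mu({t})={mu_now}")
    delta = epsilon * LN2 / mu_now
    mu_shift = traj.mu_at(t + delta)
    if mu_shift <= 0:
        raise ZeroDivisionError(f"degenerate growth: mu({t + delta})={mu_shift}")
    return LN2 / mu_shift


@dataclass(frozen=True)
class GenerationTimeSampler:
    """Truncated-normal generation-time noise model."""

    cv: float = 0.25
    min_gen: float = 0.2
    #: time-shift factor, calibrated so that the growth rate of cycles alive
    #: at t reproduces the population mu(t) under the default growth scenario
    epsilon: float = 0.65
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.cv < 0 or self.min_gen <= 0 or self.epsilon < 0:
            raise ValueError("require cv >= 0, min_gen > 0, epsilon >= 0")


def sample_generation_time(mean_tau: float, sampler: GenerationTimeSampler,
                           rng: np.random.Generator) -> float:
    """Draw a generation time ~ Normal(mean_tau, cv*mean_tau), redrawing
    until the draw is at least ``sampler.min_gen`` (rejection sampling)."""
    if mean_tau <= 0:
        raise ValueError("mean_tau must be positive")
    if sampler.cv == 0:
        return max(mean_tau, sampler.min_gen)
    sd = sampler.cv * mean_tau
    for _ in range(sampler.max_retries):
        tau = rng.normal(mean_tau, sd)
        if tau >= sampler.min_gen:
            return float(tau)
    raise RuntimeError(
        f"generation-time sampling exceeded {sampler.max_retries} retries "
        f"(mean_tau={mean_tau}, min_gen={sampler.min_gen})")
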