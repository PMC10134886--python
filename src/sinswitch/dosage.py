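"""Gene copy number as a function of growth rate and chromosomal position.

During the replication period (C period) a locus at normalized origin
distance ``p`` (0 = oriC, 1 = terminus) is replicated at time ``p * tau_c``
after division, doubling its copy number for the remainder of the cycle.
Slow growth stretches the cell cycle more than the C period, so
terminus-proximal genes spend a larger fraction of the cycle at dosage 2
when growth is slow, while an ori-proximal gene sits at dosage 2 throughout.
Multifork replication is not modeled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeneLocus",
    "CopyNumberSchedule",
    "c_period",
    "average_copy_number",
    "copy_number_at",
    "make_schedule",
    "DEFAULT_LOCI",
]

#: C-period parameters: tau_c = C_BASE + C_SLOPE / mu  (hours)
C_BASE = 0.78
C_SLOPE = 0.15

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GeneLocus:
    """A gene identified by its normalized distance from the replication origin."""

    name: str
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"locus {self.name!r}: p={self.p} outside [0, 1]")


# Default positions: slrR sits near oriC, sinI/sinR near the terminus,
# with the tapA operon in the same origin-distal chromosomal neighborhood.
DEFAULT_LOCI: dict[str, GeneLocus] = {
    "sinI": GeneLocus("sinI", 0.95),
    "sinR": GeneLocus("sinR", 0.95),
    "slrR": GeneLocus("slrR", 0.05),
    "tapA": GeneLocus("tapA", 0.90),
}


def c_period(mu: float) -> float:
    """Replication (C period) duration in hours at growth rate ``mu`` (1/h)."""
    if mu <= 0:
        raise ValueError(f"growth rate must be positive, got {mu}")
    return C_BASE + C_SLOPE / mu


@dataclass(frozen=True)
class CopyNumberSchedule:
    """Replication-timing events for one cell cycle.

    ``replication_times[name]`` is the within-cycle time at which the locus
    doubles; copy number is 1 before that time and 2 after.
    """

    tau_c: float
    tau_cyc: float
    replication_times: dict[str, float]


def make_schedule(loci: dict[str, GeneLocus], mu: float,
                  tau_cyc: float | None = None) -> CopyNumberSchedule:
    """Build the per-locus replication schedule for a cycle at growth rate ``mu``.

    ``tau_cyc`` defaults to the mean cycle length ln(2)/mu; for a stochastic
    cycle pass the sampled duration instead.
    """
    tc = c_period(mu)
    if tau_cyc is None:
        tau_cyc = LN2 / mu
    times = {name: loc.p * tc for name, loc in loci.items()}
    return CopyNumberSchedule(tau_c=tc, tau_cyc=tau_cyc, replication_times=times)


def copy_number_at(locus: GeneLocus, cell_age: float,
                   schedule: CopyNumberSchedule) -> int:
    """Instantaneous copy number (1 or 2) at ``cell_age`` within the cycle."""
    if not 0.0 <= cell_age <= schedule.tau_cyc:
        raise ValueError(
            f"cell age {cell_age} outside cycle [0, {schedule.tau_cyc}]")
    return 1 if cell_age < locus.p * schedule.tau_c else 2

def average_copy_number(locus: GeneLocus, mu: float) -> float:
    """Cycle-averaged copy number, geometric-mean form ``2**(1 - p*tau_c/tau_cyc)``.

    Reduces to ``2**(1 - tau_c/tau_cyc)`` for a terminus-proximal gene (p = 1)
    and to 2 for an ori-proximal gene (p = 0).  This form is exact under an
    exponential distribution of cell ages; the arithmetic time average over a
    single cycle is ``2 - p*tau_c/tau_cyc``.  Values are clipped to [1, 2];
    if replication of the locus would not finish within the mean cycle
    (p*tau_c > tau_cyc) a warning is raised and the value clamps to 1.
    """
    if mu <= 0:
        raise ValueError(f"growth rate must be positive, got {mu}")
    tau_c = c_period(mu)
    tau_cyc = LN2 / mu
    frac = locus.p * tau_c / tau_cyc
    if frac > 1.0:
        warnings.warn(
            f"locus {locus.name!r}: replication time p*tau_c={locus.p * tau_c:.3f} h "
            f"exceeds mean cycle {tau_cyc:.3f} h at mu={mu}; dosage clamped to 1 "
            "(multifork replication not modeled)",
            stacklevel=2,
        )
    return float(np.clip(2.0 ** (1.0 - frac), 1.0, 2.0))
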