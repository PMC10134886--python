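"""Cell-fate classification and population statistics.

A cell observed at time t is *sporulating* if the growth rate of the cycle
in force is below a threshold (default 0.17 1/h) and *matrix-on* if its
TapA reporter count strictly exceeds a threshold (default 500 molecules).
Population summaries decompose mean expression into the expressing fraction
and the mean level of expressing cells, overall and by sporulation status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stochastic import LineageRecord

__all__ = [
    "FateThresholds",
    "PopulationSummary",
    "classify_cells",
    "summarize_population",
    "mean_dynamics",
    "smoothed_argmax",
    "OBSERVATION_TIMES",
]

#: standard observation times (h after culture start): T4, T6, T8, T12
OBSERVATION_TIMES = {"T4": 4.0, "T6": 6.0, "T8": 8.0, "T12": 12.0}


@dataclass(frozen=True)
class FateThresholds:
    mu_spo: float = 0.17        # sporulation growth-rate threshold (1/h)
    tapa_on: float = 500.0      # matrix-on threshold (molecules, strict >)
    observation_time: float = 8.0

    def __post_init__(self) -> None:
        if self.mu_spo <= 0 or self.tapa_on < 0:
            raise ValueError("mu_spo must be > 0 and tapa_on >= 0")


def _at_time(records: list[LineageRecord], t: float):
    times = records[0].sample_times
    idx = np.flatnonzero(np.isclose(times, t, atol=1e-9))
    if idx.size == 0:
        raise ValueError(f"no sample at observation time {t} h")
    i = int(idx[0])
    tapa = np.array([r.species_counts("T")[i] for r in records])
    mu = np.array([r.mu_at[i] for r in records])
    return tapa, mu


def classify_cells(records: list[LineageRecord],
                   thresholds: FateThresholds = FateThresholds()) -> pd.DataFrame:
    """Per-cell labels at the observation time.

    Returns a DataFrame with columns ``tapa`` (count), ``mu`` (1/h),
    ``spo`` (bool) and ``on`` (bool, strict > threshold).
    """
    if not records:
        raise ValueError("empty ensemble")
    tapa, mu = _at_time(records, thresholds.observation_time)
    return pd.DataFrame({
        "tapa": tapa,
        "mu": mu,
        "spo": mu < thresholds.mu_spo,
        "on": tapa > thresholds.tapa_on,
    })


@dataclass(frozen=True)
class PopulationSummary:
    fraction_on_all: float
    fraction_on_spo: float      # NaN when no sporulating cells
    fraction_on_nonspo: float
    fraction_spo: float
    mean_tapa_all: float
    mean_tapa_on: float         # NaN when no expressing cells
    mean_tapa_off: float
    n_cells: int
    hist_edges: np.ndarray = field(repr=False)
    hist_counts: np.ndarray = field(repr=False)


def summarize_population(labels: pd.DataFrame, bin_width: float = 500.0
                         ) -> PopulationSummary:
    """Fractions, conditional means and the expression histogram.

    The first histogram bin [0, bin_width] holds the non-expressing cells
    (displayed broken-axis in single-cell expression figures); conditional
    means over empty subgroups are reported as NaN, never zero.
    """
    if labels.empty:
        raise ValueError("empty label table")
    on, spo, tapa = labels["on"], labels["spo"], labels["tapa"].to_numpy(float)
    n = len(labels)
    top = max(bin_width * 2, bin_width * math.ceil(tapa.max() / bin_width + 1e-12))
    edges = np.arange(0.0, top + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(tapa, bins=edges)

    def _mean(mask) -> float:
        return float(tapa[np.asarray(mask)].mean()) if mask.any() else float("nan")

    return PopulationSummary(
        fraction_on_all=float(on.mean()),
        fraction_on_spo=float(on[spo].mean()) if spo.any() else float("nan"),
        fraction_on_nonspo=float(on[~spo].mean()) if (~spo).any() else float("nan"),
        fraction_spo=float(spo.mean()),
        mean_tapa_all=float(tapa.mean()),
        mean_tapa_on=_mean(on),
        mean_tapa_off=_mean(~on),
        n_cells=n,
        hist_edges=edges,
        hist_counts=counts,
    )


def mean_dynamics(records: list[LineageRecord], n_boot: int = 1000,
                  seed: int = 0, tapa_on: float = 500.0) -> pd.DataFrame:
    """Population-mean TapA and expressing fraction over time.

    Returns a DataFrame indexed by time with columns ``mean_tapa``,
    ``ci_low``/``ci_high`` (bootstrap 95% band over lineages),
    ``fraction_on`` and ``mean_tapa_on``.
    """
    if not records:
        raise ValueError("empty ensemble")
    times = records[0].sample_times
    for r in records:
        if not np.array_equal(r.sample_times, times):
            raise ValueError("records sampled on different grids")
    T = np.array([r.species_counts("T") for r in records], dtype=float)
    mean = T.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = len(records)
    boots = np.empty((n_boot, len(times)))
    for b in range(n_boot):
        boots[b] = T[rng.integers(0, n, n)].mean(axis=0)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    on = T > tapa_on
    frac = on.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_on = np.where(on.any(axis=0),
                           np.nansum(T * on, axis=0) / np.maximum(on.sum(axis=0), 1),
                           np.nan)
    return pd.DataFrame({
        "mean_tapa": mean, "ci_low": lo, "ci_high": hi,
        "fraction_on": frac, "mean_tapa_on": mean_on,
    }, index=pd.Index(times, name="time"))


def smoothed_argmax(series: np.ndarray, times: np.ndarray) -> float:
    """Peak time by argmax of a centered 3-point moving average
    (robust against single-sample noise in stochastic means)."""
    s = np.asarray(series, float)
    if len(s) < 3:
        return float(times[int(np.argmax(s))])
    sm = s.copy()
    sm[1:-1] = (s[:-2] + s[1:-1] + s[2:]) / 3.0
    return float(times[int(np.argmax(sm))])
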