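"""Growth-rate to Spo0A~P mapping and the Hill-repression promoter model.

The phosphorelay (KinA/KinC -> Spo0F -> Spo0B -> Spo0A) is not modeled
mechanistically here; it is wrapped as a pluggable map from (strain, growth
rate) to Spo0A~P concentration.  The default implementation is a
phenomenological decreasing sigmoid per strain,

    S(mu) = floor + amplitude / (1 + (mu / K_mu)**m),

parameterized to satisfy the relative strain behavior of the phosphorelay:
Spo0A~P rises as growth slows in every strain; the kinA deletion sits below
wild type throughout; the sda deletion sits above wild type throughout; and
the kinC deletion crosses wild type once (below it at fast growth, above it
at slow growth, KinC acting as a phosphate sink late in starvation).
A quantitative phosphorelay parameterization can be substituted by loading
an external (mu, Spo0A~P) table per strain.

Also provided: the single-promoter activation/repression Hill product used
as the alternative ("high Spo0A~P represses matrix genes directly")
hypothesis for the tapA promoter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STRAINS",
    "StrainPreset",
    "PhenomenologicalMap",
    "TabulatedMap",
    "TraditionalModelParams",
    "spo0a_of_growth",
    "traditional_promoter_activity",
    "check_monotone",
]

STRAINS = ("WT", "dkinA", "dkinC", "dsda")


@dataclass(frozen=True)
class StrainPreset:
    """Per-strain sigmoid parameters and fate-threshold override."""

    name: str
    amplitude: float
    K_mu: float
    m: float
    floor: float = 0.02
    mu_spo: float = 0.17  # sporulation growth-rate threshold (1/h)

    def __post_init__(self) -> None:
        if self.name not in STRAINS:
            raise KeyError(f"unknown strain {self.name!r}; expected one of {STRAINS}")


#: Default presets.  amplitude/K_mu/m chosen so that at slow growth
#: dsda > dkinC > WT > dkinA while at fast growth WT > dkinC (single
#: crossover), and every curve clears the switch's Spo0A~P threshold while
#: growth is still fast enough for bistability, so all strains exit the
#: bistable region at about the same growth rate.
DEFAULT_PRESETS: dict[str, StrainPreset] = {
    "WT": StrainPreset("WT", amplitude=2.2, K_mu=0.38, m=5.0),
    "dkinA": StrainPreset("dkinA", amplitude=1.1, K_mu=0.40, m=5.0),
    "dkinC": StrainPreset("dkinC", amplitude=2.8, K_mu=0.30, m=5.0),
    "dsda": StrainPreset("dsda", amplitude=3.4, K_mu=0.63, m=5.0),
}


class PhenomenologicalMap:
    """Default Spo0AMap: saturating decreasing sigmoid in growth rate."""

    provenance = "phenomenological"

    def __init__(self, presets: dict[str, StrainPreset] | None = None):
        self.presets = dict(presets or DEFAULT_PRESETS)

    def __call__(self, strain: str, mu: float | np.ndarray) -> float | np.ndarray:
        if strain not in self.presets:
            raise KeyError(f"unknown strain {strain!r}; have {sorted(self.presets)}")
        p = self.presets[strain]
        mu = np.asarray(mu, dtype=float)
        if np.any(mu < 0):
            raise ValueError("growth rate must be nonnegative")
        s = p.floor + p.amplitude / (1.0 + (mu / p.K_mu) ** p.m)
        return float(s) if s.ndim == 0 else s

    def mu_spo(self, strain: str) -> float:
        return self.presets[strain].mu_spo


class TabulatedMap:
    """Spo0AMap backed by an external (mu, spo0a) table per strain.

    The delimited file must have columns ``strain``, ``mu``, ``spo0a`` (uM);
    evaluation interpolates linearly in mu and clamps at the table ends.
    Intended for plugging in an externally computed phosphorelay solution.
    """

    provenance = "phosphorelay-ode"

    def __init__(self, table: pd.DataFrame, mu_spo: dict[str, float] | None = None):
        required = {"strain", "mu", "spo0a"}
        if not required.issubset(table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        self._curves = {
            strain: grp.sort_values("mu")[["mu", "spo0a"]].to_numpy(float)
            for strain, grp in table.groupby("strain")
        }
        for strain, xy in self._curves.items():
            if np.any(np.diff(xy[:, 1]) > 1e-9):
                raise ValueError(
                    f"strain {strain!r}: spo0a must be nonincreasing in mu")
        self._mu_spo = dict(mu_spo or {})

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "TabulatedMap":
        return cls(pd.read_csv(path, sep=None, engine="python"), **kwargs)

    def __call__(self, strain: str, mu: float | np.ndarray) -> float | np.ndarray:
        if strain not in self._curves:
            raise KeyError(f"unknown strain {strain!r}; have {sorted(self._curves)}")
        xy = self._curves[strain]
        out = np.interp(mu, xy[:, 0], xy[:, 1])
        return float(out) if np.ndim(out) == 0 else out

    def mu_spo(self, strain: str) -> float:
        return self._mu_spo.get(strain, 0.17)


def spo0a_of_growth(spo0a_map, strain: str, mu: float | np.ndarray):
    """Evaluate a Spo0AMap; thin functional wrapper over the callable contract."""
    return spo0a_map(strain, mu)


def check_monotone(spo0a_map, strain: str, mu_max: float = 1.0,
                   n: int = 1000) -> bool:
    """Contract check: Spo0A~P nonincreasing in mu on a dense grid."""
    grid = np.linspace(0.0, mu_max, n)
    vals = np.asarray(spo0a_map(strain, grid))
    return bool(np.all(np.diff(vals) <= 1e-12))


@dataclass(frozen=True)
class TraditionalModelParams:
    """Activation x repression Hill product for the tapA promoter."""

    n_t1: float = 1.5
    n_t2: float = 8.0
    K_t1: float = 0.15
    K_t2: float = 0.8

    def __post_init__(self) -> None:
        if min(self.n_t1, self.n_t2, self.K_t1, self.K_t2) <= 0:
            raise ValueError("all Hill parameters must be positive")
        if not self.K_t1 < self.K_t2:
            raise ValueError("require K_t1 < K_t2 (activate before repressing)")


def traditional_promoter_activity(
        spo0a: float | np.ndarray,
        params: TraditionalModelParams = TraditionalModelParams()):
    """Relative tapA promoter activity under direct Spo0A~P activation
    followed by high-concentration repression:

        [S]^n1 / ([S]^n1 + K1^n1) * K2^n2 / ([S]^n2 + K2^n2)

    Zero at S = 0, tends to zero as S grows, single interior maximum.
    """
    s = np.asarray(spo0a, dtype=float)
    if np.any(s < 0):
        raise ValueError("Spo0A~P concentration must be nonnegative")
    p = params
    act = s**p.n_t1 / (s**p.n_t1 + p.K_t1**p.n_t1)
    rep = p.K_t2**p.n_t2 / (s**p.n_t2 + p.K_t2**p.n_t2)
    out = np.where(s > 0, act * rep, 0.0)
    return float(out) if out.ndim == 0 else out
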