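"""Declarative SinI-SinR-SlrR reaction network.

Single source of truth for both the deterministic (concentration, uM) and
stochastic (molecule count) engines.  The network comprises transcription of
sinI (activated by Spo0A~P), sinR (constitutive), slrR and tapA (both
repressed by the SinR tetramer), translation, mRNA and protein turnover, and
the protein-protein equilibria: SinI monomer/dimer, SinR dimer/tetramer,
SinI-SinR sequestration and the SlrR2-SinR2 heterotetramer.  SlrR is treated
as predominately dimeric and is produced directly as a dimer by default;
both the SinI-SinR product stoichiometry and SlrR monomer handling are
switchable.

Rate constants are given in concentration units (uM, 1/h); conversion to
stochastic count units uses the fixed cell volume (4 fL, ~2409 molecules
per uM).

The default transcription rates and promoter half-saturations are
calibrated so that the switch is monostable-low at 0.05 uM Spo0A~P and
bistable at 1 uM under fast growth, the high branch saturates above
~0.4 uM, bistability is lost when growth slows sufficiently, and the
TapA on-state exceeds 500 molecules per cell while the off-state stays
well below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dosage import DEFAULT_LOCI, GeneLocus, average_copy_number

__all__ = [
    "AVOGADRO",
    "CELL_VOLUME_FL",
    "MOLECULES_PER_UM",
    "Reaction",
    "ReactionNetwork",
    "build_sin_network",
    "dilution_augmented_rates",
    "counts_to_uM",
    "uM_to_counts",
]

AVOGADRO = 6.02214076e23
CELL_VOLUME_FL = 4.0
#: molecules per uM at 4 fL: N_A * 4e-15 L * 1e-6 mol/L
MOLECULES_PER_UM = AVOGADRO * CELL_VOLUME_FL * 1e-15 * 1e-6

SPECIES = ("mI", "mR", "mL", "mT", "I", "I2", "L", "R2", "R4", "L2", "IR", "LR", "T")

#: monomer equivalents of SinR / SlrR carried by each species
SINR_MONOMERS = {"R2": 2, "R4": 4, "IR": 1, "LR": 2}
SLRR_MONOMERS = {"L": 1, "L2": 2, "LR": 2}


def counts_to_uM(counts, volume_fl: float = CELL_VOLUME_FL):
    return np.asarray(counts, dtype=float) / (MOLECULES_PER_UM * volume_fl / CELL_VOLUME_FL)


def uM_to_counts(conc, volume_fl: float = CELL_VOLUME_FL):
    return np.asarray(conc, dtype=float) * (MOLECULES_PER_UM * volume_fl / CELL_VOLUME_FL)


@dataclass(frozen=True)
class Reaction:
    """One reaction: mass action ('uni'/'bi'/'homo') or transcription ('tx').

    ``nu`` maps species name -> stoichiometric change.  For 'tx' the rate is
    c * copy-number(locus) * regulation-factor, where the factor is a Hill
    function of Spo0A~P (mode 'act') or of a repressor species (mode 'rep').
    """

    name: str
    kind: str
    c: float
    nu: dict[str, int]
    reactants: tuple[str, ...] = ()
    locus: str | None = None
    regulator: str | None = None  # "spo0a" or a species name
    K: float = float("nan")
    n_hill: float = 2.0
    mode: str | None = None  # "act" | "rep"

    def __post_init__(self) -> None:
        if self.kind not in ("tx", "uni", "bi", "homo"):
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.c < 0:
            raise ValueError(f"reaction {self.name}: rate constant must be >= 0")
        for sp in list(self.nu) + list(self.reactants):
            if sp not in SPECIES:
                raise ValueError(f"reaction {self.name}: unknown species {sp!r}")


@dataclass(frozen=True)
class NetworkParams:
    """Kinetic constants in concentration units (uM, 1/h)."""

    # transcription, uM mRNA per hour per gene copy at full promoter activity
    a_sinI: float = 0.0065
    a_sinR: float = 0.0052
    a_slrR: float = 0.00475
    a_tapA: float = 0.13
    # promoter regulation
    K_spo0a: float = 0.25     # Spo0A~P activation of sinI (uM)
    n_act: float = 2.0
    K_rep_slrR: float = 0.0065  # SinR4 repression of slrR (uM)
    K_rep_tapA: float = 0.008   # SinR4 repression of tapA (uM)
    n_rep: float = 2.0
    leak_slrR: float = 0.0   # basal slrR promoter activity under full repression
    # translation / turnover
    k_translate: float = 200.0
    k_deg_mrna: float = 8.3
    k_deg_protein: float = 0.2
    k_deg_slrr: float = 0.6
    #: the TapA readout models the proteolytically unstable reporter
    #: (ssrA-tagged GFP), not the stable native protein
    k_deg_tapa: float = 3.0
    # protein-protein kinetics
    kon_I2: float = 384.6    # 2 I -> I2 (1/uM/h)
    koff_I2: float = 5.0
    kon_R4: float = 384.6    # 2 R2 -> R4
    koff_R4: float = 5.0
    kon_IR: float = 384.6    # I2 + R2 -> 2 IR
    krev_IR: float = 3.846   # 2 IR -> I2 + R2 (1/uM/h)
    kon_LR: float = 384.6    # L2 + R2 -> LR
    koff_LR: float = 0.5
    #: if True, degradation of the SlrR moiety of the heterotetramer releases
    #: free SinR2; default assumes the targeted complex is degraded whole.
    lr_releases_sinr: bool = False
    kon_L2: float = 200.0    # 2 L -> L2 (slrr_monomer variant only)
    koff_L2: float = 5.0


@dataclass(frozen=True)
class ReactionNetwork:
    """Immutable network: species, reactions, loci, volume, provenance."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    loci: dict[str, GeneLocus]
    params: NetworkParams
    volume_fl: float = CELL_VOLUME_FL
    variant_ir: str = "heterodimer"
    slrr_monomer: bool = False
    slrr_regulated: bool = True
    provenance: dict[str, str] = field(default_factory=dict, repr=False)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    # ---------------------------------------------------------------- totals
    def total_sinr(self, x: np.ndarray) -> float | np.ndarray:
        """Total SinR in monomer equivalents (works on counts or uM)."""
        x = np.asarray(x, dtype=float)
        return sum(w * x[..., self.species_index(s)] for s, w in SINR_MONOMERS.items())

    def total_slrr(self, x: np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(w * x[..., self.species_index(s)] for s, w in SLRR_MONOMERS.items())

    # --------------------------------------------------- deterministic engine
    def compiled(self) -> "_CompiledNetwork":
        return _CompiledNetwork(self)

    def without_slrr_regulation(self) -> "ReactionNetwork":
        """Variant with SinR4 repression of slrR removed (constitutive slrR)."""
        rxns = tuple(
            replace(r, regulator=None, mode=None, K=float("nan"))
            if r.name == "tx_slrR" else r
            for r in self.reactions
        )
        return replace(self, reactions=rxns, slrr_regulated=False)

    def zeroed_transcription(self) -> "ReactionNetwork":
        rxns = tuple(replace(r, c=0.0) if r.kind == "tx" else r
                     for r in self.reactions)
        return replace(self, reactions=rxns)


class _CompiledNetwork:
    """Array form of the network for fast propensity evaluation."""

    def __init__(self, net: ReactionNetwork):
        self.net = net
        sp = {s: i for i, s in enumerate(net.species)}
        R, S = len(net.reactions), len(net.species)
        self.nu = np.zeros((R, S), dtype=np.int64)
        self.c = np.zeros(R)
        self.kind = np.zeros(R, dtype=np.int8)  # 0 tx, 1 uni, 2 bi, 3 homo
        self.idx1 = np.full(R, -1, dtype=np.int64)
        self.idx2 = np.full(R, -1, dtype=np.int64)
        self.reg = np.full(R, -1, dtype=np.int64)  # species index; -2 = spo0a
        self.K = np.full(R, np.nan)
        self.n_hill = np.full(R, 2.0)
        self.mode_act = np.zeros(R, dtype=bool)
        self.locus_idx = np.full(R, -1, dtype=np.int64)
        self.locus_names = sorted(net.loci)
        self.locus_p = np.array([net.loci[n].p for n in self.locus_names])
        kinds = {"tx": 0, "uni": 1, "bi": 2, "homo": 3}
        for j, r in enumerate(net.reactions):
            for s, dv in r.nu.items():
                self.nu[j, sp[s]] = dv
            self.c[j] = r.c
            self.kind[j] = kinds[r.kind]
            if r.kind in ("uni", "homo"):
                self.idx1[j] = sp[r.reactants[0]]
            elif r.kind == "bi":
                self.idx1[j], self.idx2[j] = sp[r.reactants[0]], sp[r.reactants[1]]
            if r.kind == "tx":
                self.locus_idx[j] = self.locus_names.index(r.locus)
                if r.regulator == "spo0a":
                    self.reg[j] = -2
                elif r.regulator is not None:
                    self.reg[j] = sp[r.regulator]
                self.K[j] = r.K
                self.n_hill[j] = r.n_hill
                self.mode_act[j] = r.mode == "act"
        self.nu_T = self.nu.T.astype(float)

    def dose_factors(self, mu: float) -> np.ndarray:
        """Cycle-averaged copy number per locus (deterministic engine)."""
        return np.array([
            average_copy_number(self.net.loci[n], mu) for n in self.locus_names
        ])

    def rates(self, x: np.ndarray, mu: float, spo0a: float) -> np.ndarray:
        """Reaction rate vector at concentration state ``x`` (uM, uM/h)."""
        x = np.clip(x, 0.0, None)
        r = np.empty(len(self.c))
        dose = self.dose_factors(mu) if mu > 0 else np.ones(len(self.locus_names))
        for j in range(len(self.c)):
            k = self.kind[j]
            if k == 0:
                f = self.c[j] * dose[self.locus_idx[j]]
                if self.reg[j] == -2:
                    s = spo0a
                    f *= s**self.n_hill[j] / (s**self.n_hill[j] + self.K[j]**self.n_hill[j]) if s > 0 else 0.0
                elif self.reg[j] >= 0:
                    y = x[self.reg[j]]
                    Kh = self.K[j] ** self.n_hill[j]
                    f *= Kh / (y**self.n_hill[j] + Kh)
                r[j] = f
            elif k == 1:
                r[j] = self.c[j] * x[self.idx1[j]]
            elif k == 2:
                r[j] = self.c[j] * x[self.idx1[j]] * x[self.idx2[j]]
            else:
                r[j] = self.c[j] * x[self.idx1[j]] ** 2
        return r

    def rhs(self, x: np.ndarray, mu: float, spo0a: float) -> np.ndarray:
        """ODE right-hand side including growth dilution of every species."""
        return self.nu_T @ self.rates(x, mu, spo0a) - mu * np.clip(x, 0.0, None)


def build_sin_network(params: NetworkParams | dict | None = None, *,
                      loci: dict[str, GeneLocus] | None = None,
                      variant_ir: str = "heterodimer",
                      slrr_monomer: bool = False) -> ReactionNetwork:
    """Assemble the SinI-SinR-SlrR network.

    ``variant_ir`` selects the SinI-SinR sequestration stoichiometry:
    'heterodimer' (I2 + R2 <-> 2 I.R, default) or 'i2r2'
    (I2 + R2 <-> I2R2 complex, stored in the same IR slot).
    ``slrr_monomer=True`` produces SlrR as a monomer with explicit
    dimerization instead of direct dimer production.
    """
    if params is None:
        params = NetworkParams()
    elif isinstance(params, dict):
        params = NetworkParams(**params)
    loci = dict(loci or DEFAULT_LOCI)
    p = params
    prov = {"source": "package defaults, calibrated to the printed bistability anchors"}

    rxns: list[Reaction] = [
        Reaction("tx_sinI", "tx", p.a_sinI, {"mI": 1}, locus="sinI",
                 regulator="spo0a", K=p.K_spo0a, n_hill=p.n_act, mode="act"),
        Reaction("tx_sinR", "tx", p.a_sinR, {"mR": 1}, locus="sinR"),
        Reaction("tx_slrR", "tx", p.a_slrR * (1 - p.leak_slrR), {"mL": 1},
                 locus="slrR", regulator="R4", K=p.K_rep_slrR,
                 n_hill=p.n_rep, mode="rep"),
        Reaction("tx_tapA", "tx", p.a_tapA, {"mT": 1}, locus="tapA",
                 regulator="R4", K=p.K_rep_tapA, n_hill=p.n_rep, mode="rep"),
        Reaction("deg_mI", "uni", p.k_deg_mrna, {"mI": -1}, ("mI",)),
        Reaction("deg_mR", "uni", p.k_deg_mrna, {"mR": -1}, ("mR",)),
        Reaction("deg_mL", "uni", p.k_deg_mrna, {"mL": -1}, ("mL",)),
        Reaction("deg_mT", "uni", p.k_deg_mrna, {"mT": -1}, ("mT",)),
        Reaction("tl_sinI", "uni", p.k_translate, {"I": 1}, ("mI",)),
        Reaction("tl_sinR", "uni", p.k_translate, {"R2": 1}, ("mR",)),
        Reaction("tl_tapA", "uni", p.k_translate, {"T": 1}, ("mT",)),
        Reaction("dim_I", "homo", p.kon_I2, {"I": -2, "I2": 1}, ("I",)),
        Reaction("undim_I", "uni", p.koff_I2, {"I": 2, "I2": -1}, ("I2",)),
        Reaction("tet_R", "homo", p.kon_R4, {"R2": -2, "R4": 1}, ("R2",)),
        Reaction("untet_R", "uni", p.koff_R4, {"R2": 2, "R4": -1}, ("R4",)),
        Reaction("bind_LR", "bi", p.kon_LR, {"L2": -1, "R2": -1, "LR": 1},
                 ("L2", "R2")),
        Reaction("unbind_LR", "uni", p.koff_LR, {"L2": 1, "R2": 1, "LR": -1},
                 ("LR",)),
        Reaction("deg_I", "uni", p.k_deg_protein, {"I": -1}, ("I",)),
        Reaction("deg_I2", "uni", p.k_deg_protein, {"I2": -1}, ("I2",)),
        Reaction("deg_R2", "uni", p.k_deg_protein, {"R2": -1}, ("R2",)),
        Reaction("deg_R4", "uni", p.k_deg_protein, {"R4": -1}, ("R4",)),
        Reaction("deg_L2", "uni", p.k_deg_slrr, {"L2": -1}, ("L2",)),
        Reaction("deg_IR", "uni", p.k_deg_protein, {"IR": -1}, ("IR",)),
        # SlrR moiety of the heterotetramer decays fast; by default the
        # complex is removed whole (set lr_releases_sinr for SinR2 release).
        Reaction("deg_LR_slrr", "uni", p.k_deg_slrr,
                 {"LR": -1, "R2": 1} if p.lr_releases_sinr else {"LR": -1},
                 ("LR",)),
        Reaction("deg_LR", "uni", p.k_deg_protein, {"LR": -1}, ("LR",)),
        Reaction("deg_T", "uni", p.k_deg_tapa, {"T": -1}, ("T",)),
    ]

    if variant_ir == "heterodimer":
        rxns += [
            Reaction("bind_IR", "bi", p.kon_IR, {"I2": -1, "R2": -1, "IR": 2},
                     ("I2", "R2")),
            Reaction("unbind_IR", "homo", p.krev_IR, {"I2": 1, "R2": 1, "IR": -2},
                     ("IR",)),
        ]
    elif variant_ir == "i2r2":
        rxns += [
            Reaction("bind_IR", "bi", p.kon_IR, {"I2": -1, "R2": -1, "IR": 1},
                     ("I2", "R2")),
            Reaction("unbind_IR", "uni", p.krev_IR, {"I2": 1, "R2": 1, "IR": -1},
                     ("IR",)),
        ]
    else:
        raise ValueError(f"unknown variant_ir {variant_ir!r}")

    if p.leak_slrR > 0:
        rxns.append(Reaction("tx_slrR_basal", "tx", p.a_slrR * p.leak_slrR,
                             {"mL": 1}, locus="slrR"))

    if slrr_monomer:
        rxns += [
            Reaction("tl_slrR", "uni", p.k_translate, {"L": 1}, ("mL",)),
            Reaction("dim_L", "homo", p.kon_L2, {"L": -2, "L2": 1}, ("L",)),
            Reaction("undim_L", "uni", p.koff_L2, {"L": 2, "L2": -1}, ("L2",)),
            Reaction("deg_L", "uni", p.k_deg_slrr, {"L": -1}, ("L",)),
        ]
    else:
        rxns.append(
            Reaction("tl_slrR", "uni", p.k_translate, {"L2": 1}, ("mL",)))

    return ReactionNetwork(
        species=SPECIES, reactions=tuple(rxns), loci=loci, params=p,
        variant_ir=variant_ir, slrr_monomer=slrr_monomer, provenance=prov)


def dilution_augmented_rates(network: ReactionNetwork, mu: float) -> dict[str, float]:
    """Effective per-species first-order loss (degradation + dilution, 1/h).

    This is the loss the deterministic engine applies; the stochastic engine
    uses the bare degradation rates only, dilution being realized physically
    by division and binomial partitioning.
    """
    if mu < 0:
        raise ValueError("growth rate must be nonnegative")
    p = network.params
    base = {}
    for s in network.species:
        if s.startswith("m"):
            base[s] = p.k_deg_mrna
        elif s in ("L", "L2"):
            base[s] = p.k_deg_slrr
        elif s == "LR":
            base[s] = p.k_deg_slrr + p.k_deg_protein
        elif s == "T":
            base[s] = p.k_deg_tapa
        else:
            base[s] = p.k_deg_protein
    return {s: k + mu for s, k in base.items()}
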