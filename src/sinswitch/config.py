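"""Scenario configuration and pipeline orchestration.

A scenario ties together a growth condition ("normal" or "slow"), a strain
list, the reaction network, the Spo0A~P map, fate thresholds, the sampling
grid and the ensemble size, all under one root seed.  ``run_experiment``
executes growth -> Spo0A~P -> stochastic lineages -> fate summaries and
writes delimited tables plus a JSON manifest that fully determines
reproduction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deterministic import low_state
from .fate import FateThresholds, classify_cells, mean_dynamics, summarize_population
from .growth import GenerationTimeSampler, GrowthParams, simulate_growth
from .network import NetworkParams, ReactionNetwork, build_sin_network, uM_to_counts
from .spo0a import DEFAULT_PRESETS, PhenomenologicalMap, StrainPreset, TabulatedMap
from .stochastic import simulate_ensemble

log = logging.getLogger("sinswitch")

GROWTH_SCENARIOS = ("normal", "slow")


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "normal"
    strains: tuple[str, ...] = ("WT",)
    n_lineages: int = 200
    t_end: float = 14.0
    sample_dt: float = 0.5
    seed: int = 1
    slow_factor: float = 3.0
    growth: GrowthParams = field(default_factory=GrowthParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    presets: dict[str, StrainPreset] = field(
        default_factory=lambda: dict(DEFAULT_PRESETS))
    thresholds: FateThresholds = field(default_factory=FateThresholds)
    sampler: GenerationTimeSampler = field(default_factory=GenerationTimeSampler)
    spo0a_table: str | None = None   # optional external phosphorelay table
    freeze_mu_after: float | None = None
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.scenario not in GROWTH_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        unknown = set(self.strains) - set(self.presets)
        if unknown:
            raise ValueError(f"strains without presets: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "growth" in kwargs:
            kwargs["growth"] = GrowthParams(**kwargs["growth"])
        if "network" in kwargs:
            kwargs["network"] = NetworkParams(**kwargs["network"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = FateThresholds(**kwargs["thresholds"])
        if "sampler" in kwargs:
            kwargs["sampler"] = GenerationTimeSampler(**kwargs["sampler"])
        if "presets" in kwargs:
            kwargs["presets"] = {
                name: StrainPreset(name=name, **p)
                for name, p in kwargs["presets"].items()}
        if "strains" in kwargs:
            kwargs["strains"] = tuple(kwargs["strains"])
        return cls(**kwargs)

    def growth_params(self) -> GrowthParams:
        if self.scenario == "slow":
            return self.growth.scaled_nutrient(self.slow_factor)
        return self.growth

    def spo0a_map(self):
        if self.spo0a_table is not None:
            return TabulatedMap.from_file(self.spo0a_table)
        return PhenomenologicalMap(self.presets)

    def manifest(self) -> dict:
        return {
            "package_version": __version__,
            "scenario": self.scenario,
            "strains": list(self.strains),
            "n_lineages": self.n_lineages,
            "t_end": self.t_end,
            "sample_dt": self.sample_dt,
            "seed": self.seed,
            "slow_factor": self.slow_factor,
            "freeze_mu_after": self.freeze_mu_after,
            "growth": dataclasses.asdict(self.growth),
            "network": dataclasses.asdict(self.network),
            "presets": {k: dataclasses.asdict(v) for k, v in self.presets.items()},
            "thresholds": dataclasses.asdict(self.thresholds),
            "sampler": {k: v for k, v in dataclasses.asdict(self.sampler).items()},
            "spo0a_map": ("phosphorelay-ode" if self.spo0a_table
                          else "phenomenological"),
        }


def run_experiment(config: ScenarioConfig,
                   net: ReactionNetwork | None = None) -> dict:
    """Execute the full pipeline for every strain in the scenario.

    Returns a dict with the growth table, per-strain dynamics and fate
    summaries, and writes them under ``config.outdir`` together with a JSON
    manifest.  Deterministic for a fixed config (byte-identical tables).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if net is None:
        net = build_sin_network(config.network)
    gp = config.growth_params()
    try:
        traj = simulate_growth(gp, config.t_end + 2.0)
    except Exception as exc:
        raise RuntimeError(f"stage 'growth' failed: {exc}") from exc
    spo0a_map = config.spo0a_map()
    growth_df = pd.DataFrame({"time": traj.times, "C": traj.C, "N": traj.N,
                              "mu": traj.mu})
    growth_df.to_csv(outdir / "growth.tsv", sep="\t", index=False,
                     float_format="%.6g")

    sample_times = np.arange(0.0, config.t_end + 1e-9, config.sample_dt)
    results: dict = {"growth": growth_df, "strains": {}}
    for strain in config.strains:
        log.info("simulating strain %s (%d lineages)", strain, config.n_lineages)
        mu0 = traj.mu[0]
        x0 = np.round(uM_to_counts(
            low_state(net, mu0, float(spo0a_map(strain, mu0))))).astype(np.int64)
        try:
            recs = simulate_ensemble(
                net, traj, spo0a_map, strain, config.t_end, sample_times, x0,
                n_lineages=config.n_lineages,
                seed=config.seed + 13 * list(config.strains).index(strain),
                sampler=config.sampler,
                freeze_mu_after=config.freeze_mu_after)
        except Exception as exc:
            raise RuntimeError(f"stage 'ssa' failed for {strain}: {exc}") from exc
        dyn = mean_dynamics(recs, seed=config.seed,
                            tapa_on=config.thresholds.tapa_on)
        thr = dataclasses.replace(
            config.thresholds,
            mu_spo=getattr(config.presets.get(strain), "mu_spo",
                           config.thresholds.mu_spo),
            observation_time=min(config.thresholds.observation_time,
                                 config.t_end))
        labels = classify_cells(recs, thr)
        summary = summarize_population(labels)
        dyn.to_csv(outdir / f"dynamics_{strain}.tsv", sep="\t",
                   float_format="%.6g")
        labels.to_csv(outdir / f"cells_{strain}.tsv", sep="\t", index=False)
        results["strains"][strain] = {
            "records": recs, "dynamics": dyn, "labels": labels,
            "summary": summary,
        }
    manifest = config.manifest()
    manifest["outputs"] = sorted(p.name for p in outdir.glob("*.tsv"))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
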