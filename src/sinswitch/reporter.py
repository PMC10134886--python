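"""Synthetic dual-reporter microscopy tables and their analysis.

Emulates the statistical structure of segmented single-cell fluorescence
data: per image, each cell carries a GFP intensity (matrix-gene promoter
activity) and an mCherry intensity (forespore-specific promoter activity).
Cells are drawn from a 2x2 joint fate distribution (matrix-on x
sporulating), intensities from log-normal on/off mixture components on top
of Gaussian image background.  Image segmentation itself is out of scope;
the per-cell intensity table is the interface, and externally produced
tables in the same format can be loaded.

Analysis mirrors the standard quantification: a cell is called positive in
a channel when its mean intensity exceeds the image background mean by
``k_sigma`` background standard deviations; per-image fractions,
non-spo/spo fold changes, and a two-sample Welch t-test across images
compare strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReporterSynthParams",
    "generate_reporter_table",
    "call_expressing",
    "image_fractions",
    "fold_changes",
    "compare_strains",
]

REQUIRED_COLUMNS = ("image_id", "cell_id", "gfp_mean", "mcherry_mean",
                    "gfp_bg_mean", "gfp_bg_sd", "mch_bg_mean", "mch_bg_sd")


@dataclass(frozen=True)
class ReporterSynthParams:
    """Generator settings for one strain's imaging experiment.

    The standard design is 9 images (3 images x 3 independent cultures)
    with 600-1600 cells per image.  ``odds_ratio`` couples the two fates in
    the 2x2 joint table (1 = independent; < 1 = mutually exclusive).
    """

    n_images: int = 9
    cells_per_image: tuple[int, int] = (600, 1600)
    true_fraction_on: float = 0.17
    true_fraction_spo: float = 0.2
    odds_ratio: float = 1.0
    gfp_on_loc: float = 6.5      # log-normal location of the on component
    gfp_on_scale: float = 0.45
    gfp_off_loc: float = 1.2     # dim autofluorescence, well under threshold
    gfp_off_scale: float = 0.6
    mch_on_loc: float = 6.0
    mch_on_scale: float = 0.45
    mch_off_loc: float = 1.0
    mch_off_scale: float = 0.6
    bg_mean: float = 100.0
    bg_sd: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.true_fraction_on <= 1 and 0 <= self.true_fraction_spo <= 1):
            raise ValueError("fate fractions must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        for name in ("gfp_on_scale", "gfp_off_scale", "mch_on_scale",
                     "mch_off_scale", "bg_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def joint_fate_probabilities(p_on: float, p_spo: float, odds_ratio: float
                             ) -> np.ndarray:
    """2x2 joint P[(on, spo)] with given marginals and odds ratio.

    Solves for the (on & spo) cell of the contingency table; raises if the
    requested combination is infeasible.
    """
    if odds_ratio == 1.0:
        p11 = p_on * p_spo
    else:
        # quadratic in p11 from OR = p11*p00 / (p10*p01)
        a = odds_ratio - 1.0
        b = -(odds_ratio * (p_on + p_spo) + (1 - p_on - p_spo))
        c = odds_ratio * p_on * p_spo
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("infeasible joint fate distribution")
        p11 = (-b - np.sqrt(disc)) / (2 * a)
    joint = np.array([[1 - p_on - p_spo + p11, p_spo - p11],
                      [p_on - p11, p11]])
    if np.any(joint < -1e-12):
        raise ValueError(f"infeasible joint fate distribution: {joint}")
    return np.clip(joint, 0.0, 1.0)


def generate_reporter_table(params: ReporterSynthParams
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize a per-cell intensity table plus its ground-truth sidecar.

    Returns ``(table, truth)``: the table has the documented intensity and
    per-image background columns; the truth frame holds the latent on/spo
    labels for recovery tests.
    """
    rng = np.random.default_rng(params.rng_seed)
    joint = joint_fate_probabilities(params.true_fraction_on,
                                     params.true_fraction_spo,
                                     params.odds_ratio)
    flat = joint.ravel()  # (off,nonspo) (off,spo) (on,nonspo) (on,spo)
    rows, truths = [], []
    lo, hi = params.cells_per_image
    for img in range(params.n_images):
        n = int(rng.integers(lo, hi + 1))
        fate = rng.choice(4, size=n, p=flat)
        on = fate >= 2
        spo = (fate % 2) == 1
        gfp_bg = rng.normal(params.bg_mean, params.bg_sd / np.sqrt(200), size=1)[0]
        mch_bg = rng.normal(params.bg_mean, params.bg_sd / np.sqrt(200), size=1)[0]
        gfp = np.where(
            on,
            rng.lognormal(params.gfp_on_loc, params.gfp_on_scale, n),
            rng.lognormal(params.gfp_off_loc, params.gfp_off_scale, n),
        ) + rng.normal(gfp_bg, params.bg_sd, n)
        mch = np.where(
            spo,
            rng.lognormal(params.mch_on_loc, params.mch_on_scale, n),
            rng.lognormal(params.mch_off_loc, params.mch_off_scale, n),
        ) + rng.normal(mch_bg, params.bg_sd, n)
        rows.append(pd.DataFrame({
            "image_id": img, "cell_id": np.arange(n),
            "gfp_mean": np.clip(gfp, 0, None),
            "mcherry_mean": np.clip(mch, 0, None),
            "gfp_bg_mean": gfp_bg, "gfp_bg_sd": params.bg_sd,
            "mch_bg_mean": mch_bg, "mch_bg_sd": params.bg_sd,
        }))
        truths.append(pd.DataFrame({
            "image_id": img, "cell_id": np.arange(n), "on": on, "spo": spo}))
    return pd.concat(rows, ignore_index=True), pd.concat(truths, ignore_index=True)


def call_expressing(table: pd.DataFrame, k_sigma: float = 3.0) -> pd.DataFrame:
    """Threshold calls per channel: positive iff intensity strictly exceeds
    the image background mean + k_sigma * background SD."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks required columns: {missing}")
    out = table[["image_id", "cell_id"]].copy()
    out["on"] = table["gfp_mean"] > table["gfp_bg_mean"] + k_sigma * table["gfp_bg_sd"]
    out["spo"] = table["mcherry_mean"] > table["mch_bg_mean"] + k_sigma * table["mch_bg_sd"]
    return out


def image_fractions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-image fractions: on overall and by sporulation status."""
    def agg(g: pd.DataFrame) -> pd.Series:
        spo, on = g["spo"], g["on"]
        return pd.Series({
            "fraction_on": on.mean(),
            "fraction_spo": spo.mean(),
            "fraction_on_spo": on[spo].mean() if spo.any() else np.nan,
            "fraction_on_nonspo": on[~spo].mean() if (~spo).any() else np.nan,
            "n_cells": len(g),
        })
    return calls.groupby("image_id").apply(agg, include_groups=False)


def fold_changes(calls: pd.DataFrame) -> pd.Series:
    """Per-image non-spo/spo fold change of the expressing fraction.

    Images where the sporulating subgroup is empty or entirely
    non-expressing have an undefined ratio and are dropped (their count is
    recorded in ``.attrs['n_excluded']``)."""
    frac = image_fractions(calls)
    ratio = frac["fraction_on_nonspo"] / frac["fraction_on_spo"]
    valid = ratio.replace([np.inf, -np.inf], np.nan).dropna()
    valid.attrs["n_excluded"] = int(len(ratio) - len(valid))
    return valid


@dataclass(frozen=True)
class StrainComparison:
    fold_a: pd.Series = field(repr=False)
    fold_b: pd.Series = field(repr=False)
    mean_fold_a: float = float("nan")
    mean_fold_b: float = float("nan")
    sd_fold_a: float = float("nan")
    sd_fold_b: float = float("nan")
    t_statistic: float = float("nan")
    p_value: float = float("nan")


def compare_strains(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                    equal_var: bool = False) -> StrainComparison:
    """Two-sample comparison of per-image fold changes between strains
    (Welch's t-test by default, n = images per group)."""
    fa, fb = fold_changes(calls_a), fold_changes(calls_b)
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("need at least 2 valid images per strain")
    t, p = stats.ttest_ind(fa, fb, equal_var=equal_var)
    return StrainComparison(
        fold_a=fa, fold_b=fb,
        mean_fold_a=float(fa.mean()), mean_fold_b=float(fb.mean()),
        sd_fold_a=float(fa.std(ddof=1)), sd_fold_b=float(fb.std(ddof=1)),
        t_statistic=float(t), p_value=float(p))
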