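"""Rotarod and Western-blot table preparation and group analysis.

Mirrors the analysis conventions of the motor-learning experiment:

* per-animal **peak performance per day** (or median, which gives similar
  results) is the display quantity for rotarod learning curves;
* display values are **normalized to the vehicle-treated wild-type mean**
  (day-1 peak) to absorb across-cohort variability, while all statistics
  run on **raw** latencies;
* ERK activation is the densitometric ratio of phosphorylated to total
  ERK1/2, with the 42 and 44 kDa bands summed; actin is a loading control
  carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import rm_mixed_anova


def peak_daily_performance(trials: pd.DataFrame, mode: str = "peak",
                           ) -> pd.DataFrame:
    """Per-animal per-day summary of rotarod latencies.

    ``mode`` is ``"peak"`` (maximum latency across the day's trials) or
    ``"median"``.  Raises if any animal lacks trials on a day on which other
    animals were trained.
    """
    if mode not in ("peak", "median"):
        raise ValidationError(f"unknown mode {mode!r}")
    days = sorted(trials["day"].unique())
    animals = trials["animal_id"].unique()
    have = trials.groupby(["animal_id", "day"]).size()
    missing = [(a, d) for a in animals for d in days if (a, d) not in have.index]
    if missing:
        raise ValidationError(
            f"animals missing training days (animal, day): {missing}")
    agg = "max" if mode == "peak" else "median"
    out = (trials.groupby(["animal_id", "genotype", "treatment", "litter",
                           "day"], sort=True)["latency_s"]
           .agg(agg).reset_index(name="latency_s"))
    return out


def normalize_to_reference_mean(values: pd.Series, groups: pd.Series,
                                reference_group) -> pd.Series:
    """Divide every value by the mean of the reference group's values."""
    mask = groups == reference_group
    if not mask.any():
        raise ValidationError(
            f"reference group {reference_group!r} is empty")
    ref_mean = float(values[mask].mean())
    if ref_mean == 0:
        raise ValidationError("reference group mean is zero")
    return values / ref_mean


def erk_activation_ratio(samples: pd.DataFrame) -> pd.Series:
    """p-ERK / total-ERK ratio with the 42 and 44 kDa bands summed.

    ``samples`` needs columns ``pERK_42``, ``pERK_44``, ``totalERK_42``,
    ``totalERK_44``; any actin column is ignored (loading control only).
    """
    total = samples["totalERK_42"] + samples["totalERK_44"]
    if (total <= 0).any():
        bad = samples.loc[total <= 0, "animal_id"].tolist() \
            if "animal_id" in samples.columns else total.index[total <= 0].tolist()
        raise ValidationError(f"zero total-ERK density for: {bad}")
    return (samples["pERK_42"] + samples["pERK_44"]) / total


@dataclass(frozen=True)
class RotarodAnalysis:
    """ANOVA table on raw latencies plus normalized peaks for display."""

    anova: pd.DataFrame
    normalized_peaks: pd.DataFrame
    within_mode: str


def rotarod_group_analysis(trials: pd.DataFrame,
                           within_mode: str = "trials",
                           reference: tuple[str, str] = ("WT", "VEH"),
                           gg_correction: bool = False) -> RotarodAnalysis:
    """Genotype × treatment split-plot ANOVA plus normalized daily peaks.

    Statistics run on raw latencies: with ``within_mode="trials"`` the
    within-subject factor is the overall trial index; with
    ``within_mode="daily_peak"`` it is the day, using each animal's daily
    peak.  Litter enters as an additive between-subject blocking term.
    Separately, the per-day peak table normalized to the reference group's
    mean day-1 peak is returned for presentation.
    """
    if within_mode not in ("trials", "daily_peak"):
        raise ValidationError(f"unknown within_mode {within_mode!r}")
    cell_sizes = (trials.drop_duplicates("animal_id")
                  .groupby(["genotype", "treatment"]).size())
    if (cell_sizes < 2).any():
        raise ValidationError(
            f"need >= 2 animals per genotype x treatment cell: "
            f"{dict(cell_sizes)}")

    peaks = peak_daily_performance(trials, mode="peak")
    ref_geno, ref_treat = reference
    day1 = peaks[peaks["day"] == peaks["day"].min()]
    ref_mask = (day1["genotype"] == ref_geno) & (day1["treatment"] == ref_treat)
    if not ref_mask.any():
        raise ValidationError(f"reference group {reference!r} absent")
    ref_mean = float(day1.loc[ref_mask, "latency_s"].mean())
    if ref_mean == 0:
        raise ValidationError("reference group day-1 mean is zero")
    normalized = peaks.copy()
    normalized["latency_norm"] = normalized["latency_s"] / ref_mean

    if within_mode == "trials":
        raw = trials.copy()
        tpd = raw["trial"].max()
        # overall trial index 1..days*trials_per_day as the within factor
        raw["trial"] = (raw["day"] - 1) * tpd + raw["trial"]
        anova = rm_mixed_anova(raw, dv="latency_s", subject="animal_id",
                               within="trial",
                               between=("genotype", "treatment"),
                               litter="litter", gg_correction=gg_correction)
    else:
        anova = rm_mixed_anova(peaks, dv="latency_s", subject="animal_id",
                               within="day",
                               between=("genotype", "treatment"),
                               litter="litter", gg_correction=gg_correction)
    return RotarodAnalysis(anova=anova, normalized_peaks=normalized,
                           within_mode=within_mode)
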