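"""Synthetic study generators with known ground truth.

Three generators emulate the three data streams of a chronic-imaging motor
learning experiment:

* :func:`generate_spine_study` — per-spine annotation tables over three
  imaging timepoints (T0 baseline, T1 after four days of rotarod training,
  T2 after four further days of rest), with training-induced spine formation
  as a 1-D Poisson process, optional spatial clustering of new spines,
  differential clustered/isolated survival, filopodia contamination and
  positional jitter.
* :func:`generate_rotarod_dataset` — accelerating-rotarod trial latencies
  with genotype × treatment learning-rate effects, litter random effects and
  a 180 s ceiling (rod accelerates 5→80 rpm over 3 min).
* :func:`generate_densitometry_dataset` — Western-blot band densities
  (p-ERK and total ERK, 42 and 44 kDa, plus actin) with multiplicative
  lognormal noise and a configurable training × genotype p-ERK fold change.

Every generator is a pure function of (parameters, seed): identical inputs
reproduce the output tables bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .presets import CLUSTER_RADIUS_UM, GeneratorPreset

TIMEPOINTS = ("T0", "T1", "T2")

#: Column order of the spine-annotation table.
ANNOTATION_COLUMNS = [
    "animal_id", "genotype", "treatment", "litter", "segment_id",
    "segment_length_um", "timepoint", "position_um", "protrusion_length_um",
    "head_neck_ratio", "lateral", "occluded",
]

#: Column order of the ground-truth table.
TRUTH_COLUMNS = [
    "spine_id", "animal_id", "segment_id", "morph_class", "is_baseline",
    "true_position_um", "formed_at", "eliminated_at", "stabilized",
    "true_clustered",
]


def _place_new_spines(rng: np.random.Generator, n: int, length: float,
                      p_cluster: float) -> np.ndarray:
    """Sequentially place ``n`` new-spine positions on [0, length).

    Each spine after the first is, with probability ``p_cluster``, placed
    uniformly within the cluster radius of a randomly chosen already-placed
    new spine (rejecting draws outside the segment); otherwise uniformly on
    the segment.
    """
    positions = np.empty(n)
    for i in range(n):
        if i > 0 and rng.random() < p_cluster:
            partner = positions[rng.integers(i)]
            for _ in range(1000):
                pos = partner + rng.uniform(-CLUSTER_RADIUS_UM, CLUSTER_RADIUS_UM)
                if 0.0 <= pos < length:
                    break
            else:  # pragma: no cover - partner is inside, so this is unreachable
                pos = rng.uniform(0.0, length)
        else:
            pos = rng.uniform(0.0, length)
        positions[i] = pos
    return positions


def _true_clustered(positions: np.ndarray) -> np.ndarray:
    """Boolean mask: within the cluster radius of another new spine."""
    if len(positions) < 2:
        return np.zeros(len(positions), dtype=bool)
    d = np.abs(positions[:, None] - positions[None, :])
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1) < CLUSTER_RADIUS_UM


def generate_spine_study(preset: GeneratorPreset, n_animals: int,
                         segments_per_animal: int, seed: int,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic three-timepoint spine study for one group.

    Returns ``(annotations, ground_truth)``.  ``annotations`` holds one row
    per protrusion observation per timepoint at which it is present
    (columns :data:`ANNOTATION_COLUMNS`); ``ground_truth`` one row per
    generated protrusion with its true event labels
    (columns :data:`TRUTH_COLUMNS`).

    The observed position of a protrusion at each timepoint is its true
    position plus independent Gaussian jitter of SD ``preset.sigma_pos``,
    clipped into the segment.
    """
    if n_animals < 1:
        raise ValidationError(f"n_animals must be >= 1, got {n_animals}")
    if segments_per_animal < 1:
        raise ValidationError(
            f"segments_per_animal must be >= 1, got {segments_per_animal}")

    rng = np.random.default_rng(seed)
    ann_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    spine_counter = 0

    for a in range(n_animals):
        animal_id = f"{preset.name}_a{a + 1:02d}"
        litter = f"L{a // 2 + 1}"  # litters of ~2 animals per group
        for s in range(segments_per_animal):
            segment_id = f"{animal_id}_seg{s + 1:02d}"
            lo, hi = preset.seg_len_range
            length = rng.uniform(lo, hi)

            protrusions = []  # (true_pos, present_mask, morph, baseline, clustered)

            # Baseline spine population, uniformly distributed.
            n_base = rng.poisson(preset.baseline_density * length)
            base_pos = np.sort(rng.uniform(0.0, length, n_base))
            for pos in base_pos:
                alive_t1 = rng.random() < preset.s_baseline
                alive_t2 = alive_t1 and rng.random() < preset.s_baseline
                protrusions.append(
                    (pos, (True, alive_t1, alive_t2), "spine", True, None))

            # Training-induced new spines: Poisson along the segment.
            n_new = rng.poisson(preset.lambda_form * length / 100.0)
            new_pos = _place_new_spines(rng, n_new, length, preset.p_cluster)
            clustered = _true_clustered(new_pos)
            for pos, is_cl in zip(new_pos, clustered):
                p_surv = preset.s_clustered if is_cl else preset.s_isolated
                alive_t2 = rng.random() < p_surv
                protrusions.append(
                    (pos, (False, True, alive_t2), "spine", False, bool(is_cl)))

            # Transient filopodia, independently per timepoint.
            mean_filo = (preset.f_filopodia / max(1e-12, 1.0 - preset.f_filopodia)
                         * preset.baseline_density * length)
            for t in range(3):
                n_filo = rng.poisson(mean_filo) if preset.f_filopodia > 0 else 0
                for pos in rng.uniform(0.0, length, n_filo):
                    present = tuple(i == t for i in range(3))
                    protrusions.append((pos, present, "filopodium", False, None))

            for true_pos, present, morph, is_base, is_cl in protrusions:
                spine_counter += 1
                spine_id = f"sp{spine_counter:06d}"
                if morph == "filopodium":
                    length_um = rng.uniform(4.5, 8.0)
                    ratio = rng.uniform(0.9, 1.05)
                else:
                    length_um = rng.uniform(0.5, 3.0)
                    ratio = rng.uniform(1.3, 2.5)
                formed_at = None
                if not present[0]:
                    formed_at = TIMEPOINTS[present.index(True)]
                eliminated_at = None
                last = 2 - present[::-1].index(True)
                if last < 2:
                    eliminated_at = TIMEPOINTS[last + 1]
                stabilized = (morph == "spine" and not is_base
                              and formed_at == "T1" and present[2])
                truth_rows.append((
                    spine_id, animal_id, segment_id, morph, is_base, true_pos,
                    formed_at, eliminated_at, stabilized, is_cl,
                ))
                for t, here in enumerate(present):
                    if not here:
                        continue
                    obs_pos = true_pos + rng.normal(0.0, preset.sigma_pos)
                    obs_pos = float(np.clip(obs_pos, 0.0, np.nextafter(length, 0.0)))
                    occluded = rng.random() < preset.f_occluded
                    ann_rows.append((
                        animal_id, preset.genotype, preset.treatment, litter,
                        segment_id, length, TIMEPOINTS[t], obs_pos, length_um,
                        ratio, True, occluded,
                    ))

    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    annotations = annotations.sort_values(
        ["animal_id", "segment_id", "timepoint", "position_um"],
        kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return annotations, truth


# ---------------------------------------------------------------------------
# Rotarod
# ---------------------------------------------------------------------------

#: Latency ceiling in seconds (rod accelerates 5 -> 80 rpm over 3 min).
ROTAROD_CEILING_S = 180.0

ROTAROD_COLUMNS = ["animal_id", "genotype", "treatment", "litter",
                   "day", "trial", "latency_s"]

_DEFAULT_LEARNING = {
    # seconds gained per trial; the mutant-vehicle group learns faster and
    # SL327 removes the elevation without affecting wild types.
    ("WT", "VEH"): 5.0,
    ("WT", "SL327"): 5.0,
    ("MUT", "VEH"): 9.0,
    ("MUT", "SL327"): 5.0,
}


@dataclass(frozen=True)
class RotarodParams:
    """Parameters of the simulated rotarod learning curves.

    ``learning_rates`` maps (genotype, treatment) to the mean latency gain
    per trial in seconds; latency for overall trial index k (0-based across
    days) is ``baseline_s + rate * k + litter effect + noise``, truncated to
    [0, 180] s.
    """

    baseline_s: float = 60.0
    learning_rates: dict = field(default_factory=lambda: dict(_DEFAULT_LEARNING))
    litter_sd: float = 10.0
    noise_sd: float = 25.0
    n_litters: int = 4

    def __post_init__(self):
        if self.noise_sd < 0 or self.litter_sd < 0:
            raise ValidationError("noise_sd and litter_sd must be >= 0")
        if self.n_litters < 1:
            raise ValidationError("n_litters must be >= 1")


def generate_rotarod_dataset(params: RotarodParams,
                             n_per_group: int | dict,
                             days: int = 4, trials_per_day: int = 4,
                             seed: int = 0) -> pd.DataFrame:
    """Generate an accelerating-rotarod trial table.

    ``n_per_group`` is either one count for all four genotype × treatment
    groups or a mapping ``{(genotype, treatment): n}``.  Animals are
    assigned to litters round-robin so litters mix groups, as littermates
    do.  Latencies are truncated to [0, 180] s.
    """
    if days < 1 or trials_per_day < 1:
        raise ValidationError("days and trials_per_day must be >= 1")
    groups = list(params.learning_rates)
    if isinstance(n_per_group, dict):
        sizes = {g: n_per_group[g] for g in groups}
    else:
        sizes = {g: int(n_per_group) for g in groups}
    for g, n in sizes.items():
        if n < 1:
            raise ValidationError(f"group {g} has nonpositive size {n}")

    rng = np.random.default_rng(seed)
    litter_effects = rng.normal(0.0, params.litter_sd, params.n_litters)
    rows = []
    idx = 0
    for (genotype, treatment) in groups:
        rate = params.learning_rates[(genotype, treatment)]
        for a in range(sizes[(genotype, treatment)]):
            animal_id = f"{genotype}-{treatment}_a{a + 1:02d}"
            litter_i = idx % params.n_litters
            idx += 1
            for day in range(1, days + 1):
                for trial in range(1, trials_per_day + 1):
                    k = (day - 1) * trials_per_day + (trial - 1)
                    latency = (params.baseline_s + rate * k
                               + litter_effects[litter_i]
                               + rng.normal(0.0, params.noise_sd))
                    latency = float(np.clip(latency, 0.0, ROTAROD_CEILING_S))
                    rows.append((animal_id, genotype, treatment,
                                 f"L{litter_i + 1}", day, trial, latency))
    return pd.DataFrame(rows, columns=ROTAROD_COLUMNS)


# ---------------------------------------------------------------------------
# Densitometry
# ---------------------------------------------------------------------------

DENSITOMETRY_COLUMNS = ["animal_id", "genotype", "trained",
                        "pERK_42", "pERK_44", "totalERK_42", "totalERK_44",
                        "actin"]


@dataclass(frozen=True)
class DensitometryParams:
    """Parameters of the simulated Western-blot band densities.

    ``fold_change`` multiplies the p-ERK bands of trained mutant animals
    (the training × genotype ERK-activation effect); all bands carry
    multiplicative lognormal noise of log-SD ``sigma_log`` plus a common
    per-animal lognormal loading factor.
    """

    base_perk: tuple[float, float] = (0.9, 1.1)     # 42, 44 kDa
    base_total: tuple[float, float] = (1.8, 2.2)    # 42, 44 kDa
    base_actin: float = 1.0
    sigma_log: float = 0.25
    loading_sigma_log: float = 0.10
    fold_change: float = 1.5

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValidationError(
                f"fold_change must be > 0, got {self.fold_change}")
        if self.sigma_log < 0 or self.loading_sigma_log < 0:
            raise ValidationError("noise SDs must be >= 0")


def generate_densitometry_dataset(params: DensitometryParams,
                                  n_per_group: int | dict,
                                  seed: int = 0) -> pd.DataFrame:
    """Generate per-animal band densities for the four genotype × training cells.

    ``n_per_group`` is one count or a mapping ``{(genotype, trained): n}``
    with ``trained`` boolean.
    """
    cells = [("WT", False), ("MUT", False), ("WT", True), ("MUT", True)]
    if isinstance(n_per_group, dict):
        sizes = {c: n_per_group[c] for c in cells}
    else:
        sizes = {c: int(n_per_group) for c in cells}
    for c, n in sizes.items():
        if n < 2:
            raise ValidationError(f"group {c} needs n >= 2, got {n}")

    rng = np.random.default_rng(seed)
    rows = []
    for (genotype, trained) in cells:
        fold = params.fold_change if (trained and genotype == "MUT") else 1.0
        for a in range(sizes[(genotype, trained)]):
            label = "trained" if trained else "baseline"
            animal_id = f"{genotype}-{label}_a{a + 1:02d}"
            loading = float(np.exp(rng.normal(0.0, params.loading_sigma_log)))
            noise = np.exp(rng.normal(0.0, params.sigma_log, 5))
            p42 = params.base_perk[0] * fold * loading * noise[0]
            p44 = params.base_perk[1] * fold * loading * noise[1]
            t42 = params.base_total[0] * loading * noise[2]
            t44 = params.base_total[1] * loading * noise[3]
            actin = params.base_actin * loading * noise[4]
            rows.append((animal_id, genotype, trained, p42, p44, t42, t44, actin))
    return pd.DataFrame(rows, columns=DENSITOMETRY_COLUMNS)
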