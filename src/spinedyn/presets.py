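"""Generator presets: the parameter sets that define a simulated experimental group.

A :class:`GeneratorPreset` bundles everything the spine-study generator needs
to emulate one group of a three-timepoint chronic-imaging experiment
(baseline T0, post-training T1, follow-up T2): training-induced formation
intensity, the probability that a new spine is seeded next to another new
spine, differential survival of clustered versus isolated new spines, and
observation noise.

The catalog shipped in :data:`PRESETS` encodes the four experimental groups
of a MEK-inhibitor (SL327) study in MECP2-duplication mice and wild-type
littermates.  Formation intensities come directly from the published
spines-formed / segment counts; the survival parameters were calibrated by
Monte-Carlo simulation so that the *pipeline-measured* group means reproduce
the published per-100-μm rates (clustered-stabilized 1.1 for WT vehicle and
2.2 for mutant vehicle; total stabilized 1.0 for SL327-treated mutants).
See docs/methods.md for the calibration procedure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError

#: Arc-length radius (μm) within which two new spines count as clustered.
CLUSTER_RADIUS_UM = 9.0

_PROBABILITY_FIELDS = (
    "p_cluster", "s_clustered", "s_isolated", "f_filopodia",
    "s_baseline", "f_occluded",
)
_NONNEGATIVE_FIELDS = ("lambda_form", "baseline_density", "sigma_pos")


@dataclass(frozen=True)
class GeneratorPreset:
    """Parameters of one simulated experimental group.

    Parameters
    ----------
    name:
        Group label, e.g. ``"MUT-VEH"``.
    lambda_form:
        Expected training-induced new spines per 100 μm of dendrite
        (Poisson intensity at T1).
    p_cluster:
        Probability that a new spine is placed within ``CLUSTER_RADIUS_UM``
        of an already-placed new spine on the same segment.
    s_clustered, s_isolated:
        Survival probability to the follow-up timepoint T2 for new spines
        that are / are not within 9 μm of another new spine.
    baseline_density:
        Pre-existing spines per μm of dendrite.
    f_filopodia:
        Fraction of generated protrusions that are filopodia (long, headless,
        transient; excluded by the analysis pipeline).
    sigma_pos:
        SD (μm) of independent Gaussian positional jitter applied to each
        observation at each timepoint.
    seg_len_range:
        (min, max) segment length in μm; lengths drawn uniformly.
    s_baseline:
        Survival probability of a baseline spine across each imaging
        interval (T0→T1 and T1→T2).  1.0 freezes the baseline population.
    f_occluded:
        Probability that an observation is marked occluded (and hence
        excluded from analysis).
    genotype, treatment:
        Group metadata copied into every generated row.
    """

    name: str
    lambda_form: float
    p_cluster: float
    s_clustered: float
    s_isolated: float
    baseline_density: float
    f_filopodia: float
    sigma_pos: float
    seg_len_range: tuple[float, float] = (40.0, 120.0)
    s_baseline: float = 1.0
    f_occluded: float = 0.0
    genotype: str = "WT"
    treatment: str = "VEH"

    def __post_init__(self) -> None:
        for field in _PROBABILITY_FIELDS:
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"preset field '{field}' must be in [0, 1], got {v!r}")
        for field in _NONNEGATIVE_FIELDS:
            v = getattr(self, field)
            if v < 0:
                raise ValidationError(
                    f"preset field '{field}' must be >= 0, got {v!r}")
        lo, hi = self.seg_len_range
        if not (0 < lo <= hi):
            raise ValidationError(
                "preset field 'seg_len_range' must satisfy 0 < min <= max, "
                f"got {self.seg_len_range!r}")

    def replace(self, **kwargs) -> "GeneratorPreset":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)


def save_preset(preset: GeneratorPreset, path: str | Path) -> None:
    """Write a preset as a plain ``key: value`` text file."""
    lines = []
    for f in dataclasses.fields(preset):
        v = getattr(preset, f.name)
        if f.name == "seg_len_range":
            v = f"{v[0]},{v[1]}"
        lines.append(f"{f.name}: {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_preset(path: str | Path) -> GeneratorPreset:
    """Read a preset from a plain ``key: value`` text file."""
    fields = {f.name: f for f in dataclasses.fields(GeneratorPreset)}
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValidationError(
                f"preset file {path}, line {lineno}: expected 'key: value'")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValidationError(
                f"preset file {path}, line {lineno}: unknown field '{key}'")
        if key == "seg_len_range":
            lo, _, hi = value.partition(",")
            kwargs[key] = (float(lo), float(hi))
        elif key in ("name", "genotype", "treatment"):
            kwargs[key] = value
        else:
            kwargs[key] = float(value)
    return GeneratorPreset(**kwargs)


def _catalog() -> dict[str, GeneratorPreset]:
    # Formation intensities from the published spines-formed / segment counts
    # (mean segment length 80 um); survival parameters calibrated by
    # simulation against one published per-100-um group rate each.
    return {
        "WT-VEH": GeneratorPreset(
            name="WT-VEH", genotype="WT", treatment="VEH",
            lambda_form=2.4, p_cluster=0.55,
            s_clustered=0.800, s_isolated=0.30,
            baseline_density=0.40, f_filopodia=0.05, sigma_pos=0.10,
        ),
        "WT-SL327": GeneratorPreset(
            name="WT-SL327", genotype="WT", treatment="SL327",
            lambda_form=1.25, p_cluster=0.50,
            s_clustered=0.85, s_isolated=0.70,
            baseline_density=0.40, f_filopodia=0.05, sigma_pos=0.10,
        ),
        "MUT-VEH": GeneratorPreset(
            name="MUT-VEH", genotype="MUT", treatment="VEH",
            lambda_form=4.26, p_cluster=0.65,
            s_clustered=0.697, s_isolated=0.35,
            baseline_density=0.40, f_filopodia=0.05, sigma_pos=0.10,
        ),
        "MUT-SL327": GeneratorPreset(
            name="MUT-SL327", genotype="MUT", treatment="SL327",
            lambda_form=3.575, p_cluster=0.40,
            s_clustered=0.215, s_isolated=0.215,
            baseline_density=0.40, f_filopodia=0.05, sigma_pos=0.10,
        ),
    }


#: Calibrated presets for the four experimental groups.
PRESETS: dict[str, GeneratorPreset] = _catalog()

#: Published study layout: (n_animals, segments_per_animal) per group.
STUDY_LAYOUT: dict[str, tuple[int, int]] = {
    "WT-VEH": (4, 8),      # ~30 dendritic segments
    "WT-SL327": (7, 7),    # ~49 segments
    "MUT-VEH": (7, 8),     # ~54 segments
    "MUT-SL327": (8, 6),   # ~50 segments
}


def get_preset(name: str) -> GeneratorPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def save_catalog(path: str | Path, presets: dict[str, GeneratorPreset] | None = None) -> None:
    """Write the whole preset catalog as one ``key: value`` file with blocks."""
    presets = PRESETS if presets is None else presets
    blocks = []
    for preset in presets.values():
        lines = []
        for f in dataclasses.fields(preset):
            v = getattr(preset, f.name)
            if f.name == "seg_len_range":
                v = f"{v[0]},{v[1]}"
            lines.append(f"{f.name}: {v}")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")
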