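"""Clustered / isolated classification of stabilized new spines.

A stabilized new spine is *clustered* when its nearest qualifying
new-spine neighbor on the same dendritic segment lies closer than a
threshold arc-length distance (9 μm by default, the range over which
activated Ras spreads along the dendrite and couples neighboring spines);
at or beyond the threshold it is *isolated*.  Cross-segment neighbors never
qualify.

Two neighbor definitions are supported, because "another new spine" can
reasonably mean either of:

* ``stabilized_only`` (default) — only other *stabilized* new spines
  qualify as neighbors;
* ``any_new_spine`` — any training-associated new spine qualifies,
  whether or not it survived to follow-up.

:func:`monte_carlo_clustering_test` provides a permutation null for chance
clustering: spine counts are held fixed per segment while positions are
redrawn uniformly within each segment's analyzed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline import DendriteSegment, new_spine_mask, per_animal_rates

NEIGHBOR_MODES = ("stabilized_only", "any_new_spine")


def nearest_neighbor_distances(positions) -> np.ndarray:
    """Distance from each position to its nearest other position (1-D).

    Returns ``+inf`` for a singleton and an empty array for an empty input.
    All positions must lie on a single segment.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([np.inf])
    order = np.argsort(pos, kind="stable")
    s = pos[order]
    gaps = np.diff(s)
    left = np.concatenate(([np.inf], gaps))
    right = np.concatenate((gaps, [np.inf]))
    nn_sorted = np.minimum(left, right)
    out = np.empty(n)
    out[order] = nn_sorted
    return out


def classify_clustered(tracks: pd.DataFrame, threshold: float = 9.0,
                       neighbor_mode: str = "stabilized_only") -> pd.DataFrame:
    """Label every stabilized new spine clustered or isolated.

    Uses the post-training (T1) position of each spine.  A spine is
    clustered iff its nearest qualifying neighbor on the same segment lies
    at a distance strictly below ``threshold``; a distance exactly equal to
    the threshold counts as isolated.

    Returns a table with one row per stabilized new spine: ``track_id``,
    ``label`` and ``nn_distance_um`` (``+inf`` when no neighbor qualifies),
    plus the neighbor mode and threshold as columns for provenance.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    if neighbor_mode not in NEIGHBOR_MODES:
        raise ValidationError(
            f"unknown neighbor_mode {neighbor_mode!r}; "
            f"expected one of {NEIGHBOR_MODES}")

    is_new = new_spine_mask(tracks)
    stab = tracks[is_new & tracks["stabilized"].astype(bool)]
    neighbors = stab if neighbor_mode == "stabilized_only" else tracks[is_new]

    rows = []
    for seg_id, seg_stab in stab.groupby("segment_id", sort=True):
        seg_nb = neighbors[neighbors["segment_id"] == seg_id]
        nb_pos = seg_nb["pos_T1"].to_numpy(dtype=float)
        nb_ids = seg_nb["track_id"].to_numpy()
        for tid, pos in zip(seg_stab["track_id"], seg_stab["pos_T1"]):
            others = nb_pos[nb_ids != tid]
            nn = float(np.min(np.abs(others - pos))) if len(others) else np.inf
            rows.append({
                "track_id": tid,
                "segment_id": seg_id,
                "label": "clustered" if nn < threshold else "isolated",
                "nn_distance_um": nn,
            })
    labels = pd.DataFrame(rows, columns=["track_id", "segment_id", "label",
                                         "nn_distance_um"])
    labels["neighbor_mode"] = neighbor_mode
    labels["threshold_um"] = threshold
    return labels


def clustered_isolated_rates(labels: pd.DataFrame, tracks: pd.DataFrame,
                             segments: list[DendriteSegment]) -> pd.DataFrame:
    """Per-animal clustered and isolated stabilized rates per 100 μm.

    Extends :func:`spinedyn.pipeline.per_animal_rates` with
    ``clustered_stab_per_100um`` and ``isolated_stab_per_100um``; the two
    always sum to the overall stabilized rate.
    """
    known = set(tracks["track_id"])
    unknown = set(labels["track_id"]) - known
    if unknown:
        raise ValidationError(
            f"cluster labels reference unknown tracks: {sorted(unknown)}")
    rates = per_animal_rates(tracks, segments)
    merged = labels.merge(tracks[["track_id", "animal_id"]], on="track_id")
    counts = (merged.groupby(["animal_id", "label"]).size()
              .unstack(fill_value=0)
              .reindex(columns=["clustered", "isolated"], fill_value=0))
    rates = rates.merge(counts, left_on="animal_id", right_index=True,
                        how="left").fillna({"clustered": 0, "isolated": 0})
    denom = rates["total_analyzed_length_um"]
    rates["clustered_stab_per_100um"] = rates.pop("clustered") / denom * 100.0
    rates["isolated_stab_per_100um"] = rates.pop("isolated") / denom * 100.0
    return rates


# ---------------------------------------------------------------------------
# Monte-Carlo null for chance clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusteringTestResult:
    """Result of the permutation test for spatial clustering enrichment."""

    observed_fraction: float
    p_value: float
    null_fractions: np.ndarray
    n_perm: int
    threshold_um: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "observed_fraction": self.observed_fraction,
            "p_value": self.p_value,
            "null_mean": float(self.null_fractions.mean()),
            "n_perm": self.n_perm,
            "threshold_um": self.threshold_um,
            "seed": self.seed,
        }


def _sample_positions(rng: np.random.Generator, segment: DendriteSegment,
                      n: int) -> np.ndarray:
    """Uniform positions within a segment's analyzed intervals."""
    ivs = segment.analyzed_intervals
    lens = np.array([e - s for s, e in ivs])
    starts = np.array([s for s, _ in ivs])
    total = lens.sum()
    u = rng.uniform(0.0, total, n)
    edges = np.concatenate(([0.0], np.cumsum(lens)))
    idx = np.searchsorted(edges, u, side="right") - 1
    return starts[idx] + (u - edges[idx])


def monte_carlo_clustering_test(counts_per_segment: dict[str, int],
                                segments: list[DendriteSegment],
                                observed_clustered_fraction: float,
                                threshold: float = 9.0,
                                n_perm: int = 1000,
                                seed: int = 0) -> ClusteringTestResult:
    """Permutation test: is the observed clustered fraction above chance?

    Under the null, each segment's spine count is kept fixed while
    positions are redrawn uniformly and independently within its analyzed
    intervals; the clustered fraction (nearest-neighbor distance below
    ``threshold``) is recomputed for each of ``n_perm`` permutations.  The
    one-sided p-value uses the add-one convention
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    for seg_id, n in counts_per_segment.items():
        if n < 0:
            raise ValidationError(f"segment {seg_id} has negative count {n}")
    seg_by_id = {s.segment_id: s for s in segments}
    missing = set(counts_per_segment) - set(seg_by_id)
    if missing:
        raise ValidationError(f"counts reference unknown segments: {sorted(missing)}")
    total = sum(counts_per_segment.values())
    if total == 0:
        raise ValidationError("no spines to permute")

    rng = np.random.default_rng(seed)
    active = [(seg_by_id[sid], n) for sid, n in sorted(counts_per_segment.items())
              if n > 0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        clustered = 0
        for segment, n in active:
            pos = _sample_positions(rng, segment, n)
            nn = nearest_neighbor_distances(pos)
            clustered += int((nn < threshold).sum())
        null[b] = clustered / total
    p = (1 + int((null >= observed_clustered_fraction).sum())) / (n_perm + 1)
    return ClusteringTestResult(
        observed_fraction=float(observed_clustered_fraction),
        p_value=float(p), null_fractions=null, n_perm=n_perm,
        threshold_um=threshold, seed=seed)
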