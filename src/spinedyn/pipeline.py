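"""Spine annotation filtering, longitudinal track matching, event labels, rates.

The pipeline turns per-timepoint spine annotations into tracked spines and
per-animal rates per 100 μm of analyzed dendrite:

1. :func:`filter_annotations` applies the inclusion criteria — a protrusion
   must project at least 0.4 μm from the shaft, protrude laterally in the
   imaging plane and not be occluded — and excludes filopodia (long,
   headless protrusions) on morphological grounds.
2. :func:`match_tracks` links observations at consecutive timepoints within
   each segment by mutual-nearest-neighbor matching in 1-D arc-length
   position, within a configurable tolerance.
3. :func:`classify_events` derives formation / elimination / stabilization
   labels from each track's presence pattern across T0, T1, T2.  A "new
   spine" is absent at baseline and present after training; it is
   "stabilized" if still present at follow-up.
4. :func:`per_animal_rates` pools counts over each animal's segments and
   normalizes by total analyzed dendritic length (× 100 μm).

Positions are arc length along the dendrite path in μm, origin at the
segment's proximal end; analyzed intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .synthetic import TIMEPOINTS

logger = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "track_id", "animal_id", "genotype", "treatment", "litter", "segment_id",
    "present_T0", "present_T1", "present_T2",
    "pos_T0", "pos_T1", "pos_T2",
    "formed_at", "eliminated_at", "stabilized",
]

EXCLUSION_REASONS = ("occluded", "non-lateral", "sub-threshold protrusion",
                     "filopodium")


@dataclass
class DendriteSegment:
    """A 1-D analyzed dendritic domain.

    ``analyzed_intervals`` is a list of non-overlapping half-open
    ``[start, end)`` intervals (μm of arc length) that were well visualized
    at all timepoints; occluded stretches are simply absent from the list.
    """

    animal_id: str
    segment_id: str
    analyzed_intervals: list[tuple[float, float]]
    genotype: str = ""
    treatment: str = ""
    litter: str = ""

    def __post_init__(self):
        ivs = sorted(self.analyzed_intervals)
        for start, end in ivs:
            if not start < end:
                raise ValidationError(
                    f"segment {self.segment_id}: interval [{start}, {end}) "
                    "must have start < end")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValidationError(
                    f"segment {self.segment_id}: intervals overlap")
        self.analyzed_intervals = ivs
        if self.analyzed_length <= 0:
            raise ValidationError(
                f"segment {self.segment_id}: analyzed length must be > 0")

    @property
    def analyzed_length(self) -> float:
        return float(sum(e - s for s, e in self.analyzed_intervals))


def segments_from_annotations(annotations: pd.DataFrame) -> list[DendriteSegment]:
    """Build one whole-length segment per unique segment id in a table."""
    cols = ["animal_id", "segment_id", "segment_length_um",
            "genotype", "treatment", "litter"]
    meta = annotations[cols].drop_duplicates("segment_id")
    return [
        DendriteSegment(
            animal_id=r.animal_id, segment_id=r.segment_id,
            analyzed_intervals=[(0.0, float(r.segment_length_um))],
            genotype=r.genotype, treatment=r.treatment, litter=r.litter)
        for r in meta.itertuples()
    ]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_annotations(annotations: pd.DataFrame,
                       min_protrusion: float = 0.4,
                       filopodia_length: float = 4.0,
                       filopodia_head_ratio: float = 1.1,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion/exclusion criteria to an annotation table.

    Removes, in this priority order: occluded observations, non-lateral
    observations, protrusions shorter than ``min_protrusion`` μm, and
    filopodia (protrusion length > ``filopodia_length`` μm AND head/neck
    ratio < ``filopodia_head_ratio``, i.e. no distinct head).

    Returns ``(retained, exclusion_log)``; the log holds every removed row
    plus a ``reason`` column, so retained + excluded partition the input.
    """
    for name, v in (("min_protrusion", min_protrusion),
                    ("filopodia_length", filopodia_length),
                    ("filopodia_head_ratio", filopodia_head_ratio)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    if min_protrusion == 0:
        raise ValidationError("min_protrusion must be > 0")

    reason = pd.Series(pd.NA, index=annotations.index, dtype="string")
    occluded = annotations["occluded"].astype(bool)
    nonlateral = ~annotations["lateral"].astype(bool) & ~occluded
    short = (annotations["protrusion_length_um"] < min_protrusion) \
        & ~occluded & ~nonlateral
    filo = ((annotations["protrusion_length_um"] > filopodia_length)
            & (annotations["head_neck_ratio"] < filopodia_head_ratio)
            & ~occluded & ~nonlateral & ~short)
    reason[occluded] = "occluded"
    reason[nonlateral] = "non-lateral"
    reason[short] = "sub-threshold protrusion"
    reason[filo] = "filopodium"

    excluded = reason.notna()
    log = annotations[excluded].copy()
    log["reason"] = reason[excluded]
    retained = annotations[~excluded].copy()
    if len(log):
        logger.info("filter_annotations: excluded %d/%d observations (%s)",
                    len(log), len(annotations),
                    dict(log["reason"].value_counts()))
    return retained, log


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _optimal_pairs(a: np.ndarray, b: np.ndarray, tolerance: float,
                   ) -> list[tuple[int, int]]:
    """Minimum-total-distance bipartite matching between two position lists.

    Links the largest set of pairs (i, j) with |a[i] − b[j]| ≤ tolerance
    that minimizes the total matched distance (Hungarian algorithm on a
    tolerance-capped cost matrix).  Deterministic; on small instances it
    coincides with exhaustive minimum-cost matching by construction.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.abs(a[:, None] - b[None, :])
    big = max(1.0, tolerance) * 1e6
    cost = np.where(d <= tolerance, d, big)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= tolerance]


def _mutual_nn_pairs(a: np.ndarray, b: np.ndarray, tolerance: float,
                     ) -> list[tuple[int, int]]:
    """Iterated mutual-nearest-neighbor matching between two position lists.

    Repeatedly links pairs (i, j) with |a[i] − b[j]| ≤ tolerance that are
    each other's nearest unmatched neighbor, until no further pair links.
    Ties in distance are broken toward the smaller position, which makes the
    result deterministic.
    """
    free_a = list(range(len(a)))
    free_b = list(range(len(b)))
    pairs: list[tuple[int, int]] = []
    while free_a and free_b:
        av = a[free_a]
        bv = b[free_b]
        d = np.abs(av[:, None] - bv[None, :])
        # Tie-break: among equidistant candidates prefer the smaller position.
        nn_of_a = [free_b[min(range(len(free_b)),
                              key=lambda j: (d[i, j], bv[j]))]
                   for i in range(len(free_a))]
        nn_of_b = [free_a[min(range(len(free_a)),
                              key=lambda i: (d[i, j], av[i]))]
                   for j in range(len(free_b))]
        linked = []
        for ia, i in enumerate(free_a):
            j = nn_of_a[ia]
            jb = free_b.index(j)
            if nn_of_b[jb] == i and d[ia, jb] <= tolerance:
                linked.append((i, j))
        if not linked:
            break
        for i, j in linked:
            pairs.append((i, j))
            free_a.remove(i)
            free_b.remove(j)
    return pairs


_MATCHERS = {"optimal": _optimal_pairs, "mutual_nn": _mutual_nn_pairs}


def match_segment_tracks(observations: pd.DataFrame, tolerance: float = 1.0,
                         method: str = "optimal") -> list[dict]:
    """Match observations of a single segment into tracks.

    ``method`` selects the linking rule between consecutive timepoints:
    ``"optimal"`` (minimum-total-distance assignment, the default) or
    ``"mutual_nn"`` (iterated mutual nearest neighbors); both respect the
    distance tolerance and agree except on crossing near-ties, where the
    optimal assignment mis-assembles fewer tracks.

    Returns a list of dicts with per-timepoint presence/position.  Raises if
    the observations span more than one segment.
    """
    if tolerance <= 0:
        raise ValidationError(f"tolerance must be > 0, got {tolerance}")
    if method not in _MATCHERS:
        raise ValidationError(
            f"unknown matching method {method!r}; expected {set(_MATCHERS)}")
    match_fn = _MATCHERS[method]
    seg_ids = observations["segment_id"].unique()
    if len(seg_ids) > 1:
        raise ValidationError(
            f"observations from mixed segments in one call: {sorted(seg_ids)}")

    by_tp = {
        tp: np.sort(observations.loc[observations["timepoint"] == tp,
                                     "position_um"].to_numpy())
        for tp in TIMEPOINTS
    }
    # Tracks alive at the previous timepoint: list of dicts being extended.
    tracks: list[dict] = []
    open_tracks: list[dict] = []  # aligned with positions at previous tp
    prev_positions = np.empty(0)
    for t_idx, tp in enumerate(TIMEPOINTS):
        cur = by_tp[tp]
        if t_idx == 0:
            new_tracks = []
            for pos in cur:
                tr = {f"present_{t}": False for t in TIMEPOINTS}
                tr.update({f"pos_{t}": np.nan for t in TIMEPOINTS})
                tr["present_T0"] = True
                tr["pos_T0"] = float(pos)
                new_tracks.append(tr)
            tracks.extend(new_tracks)
            open_tracks = new_tracks
            prev_positions = cur
            continue
        pairs = match_fn(prev_positions, cur, tolerance)
        matched_cur = {j for _, j in pairs}
        next_open: list[dict] = []
        next_pos: list[float] = []
        for i, j in sorted(pairs):
            tr = open_tracks[i]
            tr[f"present_{tp}"] = True
            tr[f"pos_{tp}"] = float(cur[j])
            next_open.append(tr)
            next_pos.append(cur[j])
        for j, pos in enumerate(cur):
            if j in matched_cur:
                continue
            tr = {f"present_{t}": False for t in TIMEPOINTS}
            tr.update({f"pos_{t}": np.nan for t in TIMEPOINTS})
            tr[f"present_{tp}"] = True
            tr[f"pos_{tp}"] = float(pos)
            tracks.append(tr)
            next_open.append(tr)
            next_pos.append(pos)
        order = np.argsort(next_pos, kind="stable") if next_pos else []
        open_tracks = [next_open[k] for k in order]
        prev_positions = np.asarray(sorted(next_pos))
    return tracks


def match_tracks(observations: pd.DataFrame, tolerance: float = 1.0,
                 method: str = "optimal") -> pd.DataFrame:
    """Match a (possibly multi-segment) annotation table into spine tracks.

    Observations are grouped by segment and matched per segment; the result
    is one row per track with presence and position at each timepoint
    (columns :data:`TRACK_COLUMNS` minus the event labels, which
    :func:`classify_events` adds).  The result is independent of input row
    order.
    """
    meta_cols = ["animal_id", "genotype", "treatment", "litter"]
    rows = []
    for seg_id, seg_obs in observations.groupby("segment_id", sort=True):
        meta = seg_obs.iloc[0]
        for tr in match_segment_tracks(seg_obs, tolerance=tolerance,
                                       method=method):
            row = {c: meta[c] for c in meta_cols}
            row["segment_id"] = seg_id
            row.update(tr)
            rows.append(row)
    tracks = pd.DataFrame(rows)
    if tracks.empty:
        tracks = pd.DataFrame(columns=[c for c in TRACK_COLUMNS
                                       if c not in ("track_id", "formed_at",
                                                    "eliminated_at",
                                                    "stabilized")])
    sort_key = tracks[["pos_T0", "pos_T1", "pos_T2"]].min(axis=1) \
        if len(tracks) else []
    if len(tracks):
        tracks = tracks.assign(_k=sort_key).sort_values(
            ["segment_id", "_k"], kind="mergesort").drop(columns="_k")
    tracks.insert(0, "track_id",
                  [f"tr{k + 1:06d}" for k in range(len(tracks))])
    return tracks.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

def classify_events(tracks: pd.DataFrame) -> pd.DataFrame:
    """Derive formation / elimination / stabilization labels per track.

    ``formed_at`` is the first timepoint present unless that is T0 (baseline
    spine → no formation event); ``eliminated_at`` the first timepoint after
    the last presence, if any; ``stabilized`` means formed at T1 and still
    present at T2.
    """
    out = tracks.copy()
    present = out[[f"present_{t}" for t in TIMEPOINTS]].to_numpy(dtype=bool)
    if len(out) and not present.any(axis=1).all():
        bad = out.loc[~present.any(axis=1), "track_id"].tolist()
        raise ValidationError(f"tracks with no presence at any timepoint: {bad}")
    first = present.argmax(axis=1) if len(out) else np.empty(0, dtype=int)
    last = 2 - present[:, ::-1].argmax(axis=1) if len(out) \
        else np.empty(0, dtype=int)
    formed = [TIMEPOINTS[f] if f > 0 else None for f in first]
    eliminated = [TIMEPOINTS[l + 1] if l < 2 else None for l in last]
    out["formed_at"] = pd.array(formed, dtype="string")
    out["eliminated_at"] = pd.array(eliminated, dtype="string")
    out["stabilized"] = ((out["formed_at"] == "T1") & out["present_T2"]
                         ).fillna(False).astype(bool)
    return out


def new_spine_mask(tracks: pd.DataFrame) -> pd.Series:
    """Boolean mask of training-associated new spines (absent T0, present T1)."""
    return (tracks["formed_at"] == "T1").fillna(False)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def per_animal_rates(tracks: pd.DataFrame,
                     segments: list[DendriteSegment]) -> pd.DataFrame:
    """Per-animal formation and stabilization rates per 100 μm.

    Counts of new spines (formed at T1) and stabilized new spines are pooled
    over each animal's segments and divided by that animal's total analyzed
    dendritic length, × 100.
    """
    seg_ids = {s.segment_id for s in segments}
    missing = set(tracks["segment_id"]) - seg_ids if len(tracks) else set()
    if missing:
        raise ValidationError(
            f"tracks reference segments not provided: {sorted(missing)}")

    lengths: dict[str, float] = {}
    nseg: dict[str, int] = {}
    meta: dict[str, tuple] = {}
    for s in segments:
        lengths[s.animal_id] = lengths.get(s.animal_id, 0.0) + s.analyzed_length
        nseg[s.animal_id] = nseg.get(s.animal_id, 0) + 1
        meta.setdefault(s.animal_id, (s.genotype, s.treatment, s.litter))
    for animal, total in lengths.items():
        if total <= 0:
            raise ValidationError(f"animal {animal} has zero analyzed length")

    if len(tracks):
        is_new = new_spine_mask(tracks)
        formed = tracks[is_new].groupby("animal_id").size()
        stab = tracks[is_new & tracks["stabilized"]].groupby("animal_id").size()
    else:
        formed = stab = pd.Series(dtype=int)

    rows = []
    for animal in sorted(lengths):
        total = lengths[animal]
        g, tr, lit = meta[animal]
        n_formed = int(formed.get(animal, 0))
        n_stab = int(stab.get(animal, 0))
        rows.append({
            "animal_id": animal, "genotype": g, "treatment": tr, "litter": lit,
            "formed_per_100um": n_formed / total * 100.0,
            "stabilized_per_100um": n_stab / total * 100.0,
            "total_analyzed_length_um": total,
            "n_segments": nseg[animal],
        })
    return pd.DataFrame(rows)
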