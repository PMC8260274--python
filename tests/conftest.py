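import numpy as np
import pandas as pd
import pytest

from spinedyn import (classify_clustered, classify_events,
                      clustered_isolated_rates, filter_annotations,
                      generate_spine_study, get_preset, match_tracks,
                      segments_from_annotations)


def make_annotations(rows):
    """Build a minimal annotation table from (segment_id, timepoint,
    position) or full-ish tuples; remaining columns get benign defaults."""
    records = []
    for r in rows:
        rec = {
            "animal_id": "a1", "genotype": "WT", "treatment": "VEH",
            "litter": "L1", "segment_id": "s1", "segment_length_um": 100.0,
            "timepoint": "T1", "position_um": 0.0,
            "protrusion_length_um": 1.5, "head_neck_ratio": 1.5,
            "lateral": True, "occluded": False,
        }
        rec.update(r)
        records.append(rec)
    return pd.DataFrame(records)


def run_pipeline(annotations, **kwargs):
    """filter -> match -> classify -> cluster -> rates, returning the lot."""
    retained, log = filter_annotations(annotations)
    tracks = classify_events(match_tracks(retained, **kwargs))
    segments = segments_from_annotations(annotations)
    labels = classify_clustered(tracks)
    rates = clustered_isolated_rates(labels, tracks, segments)
    return retained, log, tracks, labels, rates


@pytest.fixture(scope="session")
def wt_veh_study():
    preset = get_preset("WT-VEH")
    return generate_spine_study(preset, n_animals=4, segments_per_animal=8,
                                seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
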