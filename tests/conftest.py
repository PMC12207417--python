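import logging

import numpy as np
import pandas as pd
import pytest

from divetrace.preprocess import sv_to_grayscale_array
from divetrace.segmentation import evaluate_segmentation, reduced_segmenter
from divetrace.simulate import (
    make_training_corpus,
    oracle_scene_config,
    simulate_scene,
)

logging.getLogger("divetrace").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def oracle_scenes():
    """50 seeded noise-free scenes: (grayscale image, truth) pairs."""
    out = []
    for seed in range(50):
        record, truth = simulate_scene(oracle_scene_config(seed))
        out.append((sv_to_grayscale_array(record.sv.T), truth))
    return out


@pytest.fixture(scope="session")
def trained_reduced_unet():
    """A reduced U-Net trained on 200 synthetic tiles plus its 50-tile
    held-out set. Session-scoped: training runs once per test session."""
    corpus = make_training_corpus(250, seed=1)
    train, test = corpus[:200], corpus[200:]
    seg = reduced_segmenter(random_state=0)
    seg.fit(
        [im for im, _ in train],
        [m for _, m in train],
        validation_data=([im for im, _ in test], [m for _, m in test]),
    )
    return seg, test


@pytest.fixture()
def simple_ledger():
    """Two observation windows of 0.5 h each with positions."""
    return pd.DataFrame(
        {
            "echogram_id": ["a", "b"],
            "vessel_id": ["V1", "V1"],
            "t_start": pd.to_datetime(["2022-01-01 00:00", "2022-01-01 01:00"]),
            "t_end": pd.to_datetime(["2022-01-01 00:30", "2022-01-01 01:30"]),
            "hours": [0.5, 0.5],
            "lat": [-60.5, -60.5],
            "lon": [-45.5, -45.4],
        }
    )


def make_events(rows):
    """Build a minimal event table from (timestamp, class, minutes, lat, lon)."""
    return pd.DataFrame(
        [
            {
                "event_id": i,
                "object_class": cls,
                "duration_min": mins,
                "duration_s": mins * 60.0,
                "timestamp": pd.Timestamp(ts),
                "lat": lat,
                "lon": lon,
                "qc_flag": "kept",
            }
            for i, (ts, cls, mins, lat, lon) in enumerate(rows)
        ]
    )
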