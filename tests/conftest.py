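import logging

import numpy as np
import pandas as pd
import pytest

from hazelhealth import (
    BandStack,
    OrchardScenario,
    compute_all,
    generate_dataset,
    segment_plant,
)

logging.getLogger("hazelhealth").setLevel(logging.ERROR)


def features_from_dataset(dataset, **vi_kwargs):
    """Segment every rendered plant and collect per-slice VI rows."""
    rows = []
    for stack, truth in dataset:
        _, _, kept = segment_plant(
            stack, plant_id=truth.plant_id, quadrant_labels=truth.quadrant_labels
        )
        rows.extend(compute_all(s).as_row() for s in kept)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def calibration_features() -> pd.DataFrame:
    """Default-profile synthetic dataset with >= 200 slices per class."""
    scenario = OrchardScenario(n_plants=90, prevalence_unhealthy=0.5, seed=0)
    df = features_from_dataset(generate_dataset(scenario))
    assert (df["label"] == 0).sum() >= 200 and (df["label"] == 1).sum() >= 200
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_stack(rng, h=32, w=32, gsd=1.0) -> BandStack:
    bands = {
        b: rng.uniform(0.01, 0.99, size=(h, w))
        for b in ("GREEN", "RED", "RED_EDGE", "NIR")
    }
    return BandStack(bands, gsd_cm_per_px=gsd)
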