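"""Shared fixtures: reference renders, averaged background, and the
desk-scale trained regressor (trained once per session and reused by the
end-to-end and interpretation tests)."""

from __future__ import annotations

import numpy as np
import pytest

from monoleaf import plantgen as pg
from monoleaf.preprocess import average_background
from monoleaf.regressor import ModelConfig, build_model, train_arrays

#: canonical desk-scale study conditions: 300 train / 50 val-free test plants,
#: 2–6 leaves, no occlusion, rendered at the 299-px working size
DESK_N_TRAIN = 300
DESK_N_TEST = 50
DESK_LEAF_RANGE = (2, 6)
DESK_EPOCHS = 30
DESK_LR = 0.003

#: curated reference fixture for the interpretation direction checks
REFERENCE_FIXTURE_SPEC = pg.SyntheticPlantSpec(
    leaf_count=2, canvas_size=(299, 299), seed=9005
)


def desk_scale_data(base_seed: int = 0):
    """Render the desk-scale train/test sets; returns arrays and test renders."""
    rng = np.random.default_rng(base_seed)

    def make(n, seed0):
        x = np.empty((n, 299, 299, 3), np.uint8)
        y = np.empty(n, np.float32)
        renders = []
        for i in range(n):
            k = int(rng.integers(DESK_LEAF_RANGE[0], DESK_LEAF_RANGE[1] + 1))
            r = pg.render_plant_detailed(
                pg.SyntheticPlantSpec(
                    leaf_count=k, canvas_size=(299, 299), seed=seed0 + i
                )
            )
            x[i] = r.image
            y[i] = k
            renders.append(r)
        return x, y, renders

    x_train, y_train, _ = make(DESK_N_TRAIN, 1000 + base_seed)
    x_test, y_test, test_renders = make(DESK_N_TEST, 9000 + base_seed)
    return x_train, y_train, x_test, y_test, test_renders


@pytest.fixture(scope="session")
def desk_model():
    """Reduced regressor trained on the canonical desk-scale dataset."""
    x_train, y_train, x_test, y_test, test_renders = desk_scale_data()
    config = ModelConfig(learning_rate=DESK_LR, epochs=DESK_EPOCHS, seed=0)
    model = build_model(config)
    train_arrays(model, x_train, y_train, epochs=DESK_EPOCHS)
    return {
        "model": model,
        "x_test": x_test,
        "y_test": y_test,
        "test_renders": test_renders,
    }


@pytest.fixture(scope="session")
def plant_render():
    """One 5-leaf reference plant at the default 512-px canvas."""
    return pg.render_plant_detailed(pg.SyntheticPlantSpec(leaf_count=5, seed=7))


@pytest.fixture(scope="session")
def avg_background():
    """Average of ten jittered background renders at the 512-px canvas."""
    return average_background(
        [pg.render_background(pg.SyntheticPlantSpec(seed=s)) for s in range(10)]
    )


@pytest.fixture(scope="session")
def reference_render():
    """The curated 299-px reference plant for interpretation checks."""
    return pg.render_plant_detailed(REFERENCE_FIXTURE_SPEC)
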