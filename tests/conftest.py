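import numpy as np
import pandas as pd
import pytest

from habsuit import Grid, OccurrenceSet, PredictorStack, Raster


@pytest.fixture
def unit_grid():
    """10x10 grid of 100-m cells anchored at the origin."""
    return Grid(0.0, 0.0, 100.0, 10, 10)


@pytest.fixture
def flat_raster(unit_grid):
    return Raster(np.zeros(unit_grid.shape), unit_grid)


def make_occurrences(xy, accuracy=50.0):
    xy = np.asarray(xy, dtype=float)
    return OccurrenceSet(
        pd.DataFrame(
            {
                "x": xy[:, 0],
                "y": xy[:, 1],
                "accuracy_m": accuracy,
                "date": "2015-01-01",
                "source": "test",
            }
        )
    )


@pytest.fixture
def clustered_points():
    """Three tight clusters plus scattered points, for thinning tests."""
    rng = np.random.default_rng(42)
    clusters = [
        rng.normal([5000, 5000], 400, size=(20, 2)),
        rng.normal([15000, 9000], 400, size=(15, 2)),
        rng.normal([9000, 16000], 400, size=(15, 2)),
    ]
    scattered = rng.uniform(0, 20000, size=(10, 2))
    return make_occurrences(np.vstack(clusters + [scattered]))


@pytest.fixture
def small_landscape():
    from habsuit.synth import gen_landscape

    return gen_landscape(size=60, seed=11, correlation_length=6.0)


def make_stack(layers, kinds=None, cellsize=100.0):
    """Stack from a dict of 2-D arrays."""
    first = next(iter(layers.values()))
    grid = Grid(0.0, 0.0, cellsize, *np.shape(first))
    stack = PredictorStack()
    for name, arr in layers.items():
        kind = (kinds or {}).get(name, "continuous")
        stack.add(name, Raster(np.asarray(arr, dtype=float), grid), kind)
    return stack
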