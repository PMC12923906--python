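import numpy as np
import pandas as pd
import pytest

from capipe.core import ArenaConfig, RecordingMeta
from capipe.synthetic import GroundTruth, simulate_trajectory


@pytest.fixture
def arena() -> ArenaConfig:
    return ArenaConfig(object_positions=((10.0, 20.0), (30.0, 20.0)))


@pytest.fixture
def meta() -> RecordingMeta:
    return RecordingMeta("S1", fps=20.0, duration_s=600.0)


@pytest.fixture
def ou_trajectory(arena, meta):
    return simulate_trajectory(arena, meta, seed=12345)


def make_truth(
    n_cells: int,
    n_place: int = 0,
    bursts: dict | None = None,
    place_gain: float = 8.0,
    base_rate_hz: float = 0.25,
    blocks: list[list[int]] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Hand-built ground truth: first ``n_place`` cells are place-tuned."""
    rng = np.random.default_rng(seed)
    place = np.arange(n_cells) < n_place
    block = np.full(n_cells, -1)
    for b, members in enumerate(blocks or []):
        block[members] = b
    cells = pd.DataFrame(
        {
            "place_cell": place,
            "tuning_x": rng.uniform(4, 36, n_cells),
            "tuning_y": rng.uniform(4, 36, n_cells),
            "tuning_width_cm": 5.0,
            "peak_gain": place_gain,
            "object_tuned": False,
            "base_rate_hz": base_rate_hz * np.exp(rng.normal(0, 0.4, n_cells) - 0.08),
            "block": block,
        },
        index=pd.RangeIndex(n_cells, name="global_id"),
    )
    active = pd.DataFrame(True, index=cells.index, columns=["HA", "S1", "S2", "S3"])
    return GroundTruth(cells, active, bursts or {}, {})
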