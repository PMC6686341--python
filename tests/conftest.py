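import numpy as np
import pytest

from firerefugia.grid import RasterGrid
from firerefugia.pipeline import PipelineConfig, SyntheticBlock, Thresholds
from firerefugia.synthetic import LandscapeConfig, generate_landscape


def small_config(seed=3, out_dir="unused"):
    """A reduced landscape and radii set that runs in seconds."""
    return PipelineConfig(
        seed=seed,
        out_dir=str(out_dir),
        thresholds=Thresholds(radii_m=(400.0, 1_200.0, 3_000.0)),
        synthetic=SyntheticBlock(
            landscape=LandscapeConfig(
                extent_m=(15_000.0, 15_000.0),
                n_fires=6,
                fire_area_km2_range=(2.0, 10.0),
            ),
            n_leks_per_category=4,
        ),
    )


@pytest.fixture(scope="session")
def small_landscape():
    """A 12 x 12 km landscape with a few fires; shared across tests."""
    cfg = LandscapeConfig(
        extent_m=(12_000.0, 12_000.0),
        n_fires=4,
        fire_area_km2_range=(2.0, 8.0),
        rng_seed=42,
    )
    return generate_landscape(cfg)


@pytest.fixture()
def flat_grid():
    """A 10 x 10 grid of 30 m cells, origin at (0, 300)."""

    def make(fill=0.0, dtype=float):
        return RasterGrid(np.full((10, 10), fill, dtype=dtype), 30.0, (0.0, 300.0))

    return make
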