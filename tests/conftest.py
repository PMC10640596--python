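import numpy as np
import pytest

from octloc.geometry import ScanGeometry
from octloc.synthetic import SynthConfig, generate_dataset
from octloc.train import Dataset


@pytest.fixture(scope="session")
def centered_geometry() -> ScanGeometry:
    """6 mm scan, 16 columns, slices through and around the fovea."""
    return ScanGeometry(
        scan_width_mm=6.0,
        slice_positions_mm=(0.0, 1.0, 2.0, 3.5),
        n_columns=16,
    )


@pytest.fixture(scope="session")
def small_synthetic() -> tuple[Dataset, SynthConfig]:
    cfg = SynthConfig(n_volumes=2, seed=7)
    samples, geom = generate_dataset(cfg)
    return Dataset.from_synthetic(samples, geom), cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
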