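import numpy as np
import pytest

from polkadots.preprocess import BinaryVolume
from polkadots.synth import SynthConfig, synthesize_cell


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def tiny_cell():
    """One small synthetic cell shared across tests (uniform vesicles)."""
    cfg = SynthConfig(
        grid_shape=(64, 64, 64),
        cell_semi_axes=(26.0, 24.0, 22.0),
        n_filaments=5,
        filament_length_dist=("uniform", 25, 70),
        curvature_bound=8.0,
        n_vesicles=12,
        seed=123,
    )
    return synthesize_cell(cfg)


def make_tube(centerline: np.ndarray, radius: int = 2, margin: int = 4) -> tuple:
    """Voxelize a float polyline into its own padded volume.

    Returns (BinaryVolume, shifted centerline points)."""
    from polkadots.synth import _voxelize_polyline

    pts = np.asarray(centerline, dtype=float)
    lo = pts.min(axis=0) - margin
    pts = pts - lo
    shape = tuple((pts.max(axis=0) + margin + 1).astype(int))
    vol = _voxelize_polyline(pts, radius, shape)
    return BinaryVolume(vol), pts


def random_curved_centerline(rng, length: int, turn_deg: float) -> np.ndarray:
    """Unit-step random walk with bounded per-step turn (free space)."""
    from polkadots.synth import _random_unit, _rotate_toward

    d = _random_unit(rng)
    pts = [np.zeros(3)]
    for _ in range(length):
        d = _rotate_toward(d, turn_deg, rng)
        pts.append(pts[-1] + d)
    return np.asarray(pts)
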