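"""TIFF and table I/O for synthetic cells and analysis outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .preprocess import BinaryVolume
from .synth import GroundTruth, SynthCell

__all__ = [
    "write_volume_tiff",
    "read_volume_tiff",
    "write_synth_cell",
    "write_ground_truth_json",
]


def write_volume_tiff(path: str | Path, volume: BinaryVolume) -> None:
    """Write a binary volume as a multi-page 8-bit TIFF (one z-plane per page)."""
    tifffile.imwrite(str(path), volume.occupancy.astype(np.uint8) * 255,
                     metadata={"voxel_pitch_nm": volume.voxel_pitch_nm})


def read_volume_tiff(path: str | Path, voxel_pitch_nm: float = 25.0) -> BinaryVolume:
    """Read a multi-page TIFF as a binary volume (nonzero -> occupied)."""
    data = tifffile.imread(str(path))
    return BinaryVolume(data > 0, voxel_pitch_nm)


def write_ground_truth_json(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "filaments": [
            {
                "centerline": pts.tolist(),
                "length_voxels": ln,
                "punctum": bool(p),
            }
            for pts, ln, p in zip(truth.centerlines, truth.lengths, truth.is_punctum)
        ],
        "vesicles": [
            {
                "center": c.tolist(),
                "radius": r,
                "n_voxels": n,
                "label": lab,
            }
            for c, r, n, lab in zip(truth.vesicle_centers, truth.vesicle_radii,
                                    truth.vesicle_voxels, truth.vesicle_labels)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def write_synth_cell(directory: str | Path, cell: SynthCell, stem: str = "cell") -> None:
    """Write one synthetic cell: one TIFF per channel plus the truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume_tiff(directory / f"{stem}_mask.tif", cell.mask)
    write_volume_tiff(directory / f"{stem}_bcl10.tif", cell.filaments)
    write_volume_tiff(directory / f"{stem}_lc3.tif", cell.vesicles)
    write_ground_truth_json(directory / f"{stem}_truth.json", cell.truth)
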