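"""Reading and writing images, height maps and analysis tables.

Fringe images travel as grayscale TIFF (8/16-bit integer or 32-bit
float) with a JSON sidecar carrying the provenance metadata (optics,
specimen, noise, seed).  Height maps are single-band 32-bit float TIFF
in nm with a sidecar recording the pixel size.  Profiles and peak sets
export to CSV; analysis reports to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .analysis import FringePeakSet, RadialProfile
from .geometry import HeightMap
from .imaging import FringeImage

__all__ = [
    "write_fringe_image",
    "read_fringe_image",
    "write_height_map",
    "read_height_map",
    "profile_to_csv",
    "peaks_to_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_fringe_image(
    img: FringeImage, path, bit_depth: int | str = 16
) -> Path:
    """Write a TIFF (8/16-bit integer or 'float') plus JSON sidecar."""
    path = Path(path)
    if bit_depth == 8:
        data = np.clip(np.round(img.data), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.clip(np.round(img.data), 0, 65535).astype(np.uint16)
    elif bit_depth == "float":
        data = img.data.astype(np.float32)
    else:
        raise ValueError("bit_depth must be 8, 16 or 'float'")
    tifffile.imwrite(path, data)
    meta = {"pixel_size_nm": img.pixel_size, "metadata": img.metadata}
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=float))
    return path


def read_fringe_image(path) -> FringeImage:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    side = _sidecar(path)
    pixel_size, metadata = 1.0, {}
    if side.exists():
        meta = json.loads(side.read_text())
        pixel_size = float(meta.get("pixel_size_nm", 1.0))
        metadata = meta.get("metadata", {})
    return FringeImage(data, pixel_size, metadata)


def write_height_map(hm: HeightMap, path, metadata: Optional[dict] = None) -> Path:
    """Write a 32-bit float TIFF (nm, NaN = undefined) plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, hm.data.astype(np.float32))
    meta = {"pixel_size_nm": hm.pixel_size, "units": "nm", "origin": "corner"}
    if metadata:
        meta["metadata"] = metadata
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=float))
    return path


def read_height_map(path) -> HeightMap:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    side = _sidecar(path)
    pixel_size = 1.0
    if side.exists():
        pixel_size = float(json.loads(side.read_text()).get("pixel_size_nm", 1.0))
    return HeightMap(data, pixel_size)


def profile_to_csv(profile: RadialProfile, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"radius_nm": profile.radii, "intensity": profile.intensities}
    ).to_csv(path, index=False)
    return path


def peaks_to_csv(peaks: FringePeakSet, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "index": peaks.antinode_index,
            "radius_nm": peaks.peak_radii,
            "z_nm": peaks.peak_heights_z,
            "amplitude": peaks.peak_amplitudes,
        }
    ).to_csv(path, index=False)
    return path
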