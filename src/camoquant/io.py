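"""Reading and writing scenes, masks and event tables.

Scenes are stored as float32 multi-channel TIFF stacks (channel axis
first) with a JSON sidecar recording channel names and the pixel
scale; masks are single-channel 8-bit PNG label images (0 = ignore,
1 = animal, 2 = background).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .spectra import CatchImage, ReceptorSet, validate_mask


def save_scene(path, img: CatchImage) -> None:
    """Write a catch image as ``<path>.tif`` plus ``<path>.json``."""
    path = Path(path)
    stack = np.stack([img.channels[n] for n in img.names]).astype(np.float32)
    tifffile.imwrite(path.with_suffix(".tif"), stack)
    meta = {"channels": list(img.names), "scale_px_per_mm": img.scale_px_per_mm}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_scene(path, receptor_set: ReceptorSet | None = None) -> CatchImage:
    path = Path(path)
    stack = tifffile.imread(path.with_suffix(".tif"))
    meta = json.loads(path.with_suffix(".json").read_text())
    channels = {n: stack[k].astype(float) for k, n in enumerate(meta["channels"])}
    return CatchImage(channels, float(meta["scale_px_per_mm"]), receptor_set)


def save_mask(path, mask: np.ndarray) -> None:
    mask = validate_mask(mask, require=())
    iio.imwrite(Path(path).with_suffix(".png"), mask.astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path).with_suffix(".png"))).astype(int)
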