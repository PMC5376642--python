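"""File interfaces: multi-channel TIFF + YAML sidecar, label masks, particle CSV.

A section on disk is a multi-page TIFF (one page per element channel) next
to a YAML sidecar carrying the pixel size, section thickness and the
page → element mapping.  Region masks travel as 8-bit label TIFFs
(0 outside, 1 interior, 2 wall, 3 background) or as polygon JSON
(``{"interior": [[row, col], ...], "wall": ..., "background": ...}``),
rasterized on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from skimage.draw import polygon as draw_polygon

from .refdb import ElementChannel, ElementMapStack
from .segmentation import CrystalParticle, RegionMasks, particles_to_frame

__all__ = [
    "write_stack",
    "read_stack",
    "write_region_masks",
    "read_region_masks",
    "polygons_to_masks",
    "read_polygon_masks",
    "write_particles_csv",
]

REGION_CODES = {"interior": 1, "wall": 2, "background": 3}


def write_stack(stack: ElementMapStack, tiff_path: str | Path) -> Path:
    """Write a stack as multi-page float32 TIFF plus a ``.yaml`` sidecar."""
    tiff_path = Path(tiff_path)
    elements = sorted(stack.channels)
    pages = np.stack(
        [stack.channels[el].intensities.astype(np.float32) for el in elements]
    )
    tifffile.imwrite(tiff_path, pages)
    sidecar = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "channels": {i: el for i, el in enumerate(elements)},
        "metadata": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else str(v))
            for k, v in stack.metadata.items()
        },
    }
    tiff_path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
    return tiff_path


def read_stack(tiff_path: str | Path) -> ElementMapStack:
    """Read a multi-page TIFF and its YAML sidecar back into a stack."""
    tiff_path = Path(tiff_path)
    sidecar = yaml.safe_load(tiff_path.with_suffix(".yaml").read_text())
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    px = float(sidecar["pixel_size_nm"])
    channels = {
        el: ElementChannel(el, pages[int(i)].astype(float), px)
        for i, el in sidecar["channels"].items()
    }
    return ElementMapStack(channels, metadata=dict(sidecar.get("metadata", {})))


def write_region_masks(masks: RegionMasks, path: str | Path) -> Path:
    """Write region masks as one 8-bit label TIFF."""
    path = Path(path)
    labels = np.zeros(masks.interior.shape, dtype=np.uint8)
    for name, m in masks.items():
        labels[m] = REGION_CODES[name]
    tifffile.imwrite(path, labels)
    return path


def read_region_masks(path: str | Path, provenance: str = "manual") -> RegionMasks:
    labels = tifffile.imread(Path(path))
    return RegionMasks(
        interior=labels == REGION_CODES["interior"],
        wall=labels == REGION_CODES["wall"],
        background=labels == REGION_CODES["background"],
        provenance=provenance,
    )


def polygons_to_masks(
    polygons: dict[str, Sequence[Sequence[float]]],
    shape: tuple[int, int],
    provenance: str = "manual",
) -> RegionMasks:
    """Rasterize region outlines given as (row, col) vertex lists.

    Later regions never overwrite earlier ones (interior > wall >
    background), keeping the masks disjoint.
    """
    taken = np.zeros(shape, dtype=bool)
    out: dict[str, np.ndarray] = {}
    for name in ("interior", "wall", "background"):
        mask = np.zeros(shape, dtype=bool)
        verts = polygons.get(name)
        if verts:
            arr = np.asarray(verts, dtype=float)
            rr, cc = draw_polygon(arr[:, 0], arr[:, 1], shape=shape)
            mask[rr, cc] = True
            mask &= ~taken
            taken |= mask
        out[name] = mask
    return RegionMasks(provenance=provenance, **out)


def read_polygon_masks(path: str | Path, shape: tuple[int, int]) -> RegionMasks:
    polygons = json.loads(Path(path).read_text())
    return polygons_to_masks(polygons, shape)


def write_particles_csv(particles: Sequence[CrystalParticle], path: str | Path) -> Path:
    path = Path(path)
    particles_to_frame(particles).to_csv(path, index=False)
    return path
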