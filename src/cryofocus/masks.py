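"""Soft-mask construction and combination.

A focused classification needs two masks: one around the region to classify
on (the focus region, V2) and one around everything else (V1).  In the
workflow this package implements, the V2 mask is typically built from a map
generated out of pseudo-atoms, converted to a soft-edged mask
(binarize -> dilate -> raised-cosine edge), and the V1 mask is the mask of
the whole complex minus the V2 mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import VolumeGrid

__all__ = ["SoftMask", "make_soft_mask", "mask_subtract", "apply_mask", "pseudo_atoms_to_map"]


@dataclass(frozen=True)
class SoftMask:
    """A [0, 1]-valued weighting volume, with the parameters that built it."""

    volume: VolumeGrid
    threshold: float | None = None
    extend_px: int = 0
    soft_edge_px: int = 0

    def __post_init__(self) -> None:
        d = self.volume.data
        if d.min() < -1e-12 or d.max() > 1.0 + 1e-12:
            raise ValueError("mask values must lie in [0, 1]")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def pixel_size(self) -> float:
        return self.volume.pixel_size

    @property
    def box(self) -> int:
        return self.volume.box


def _check_same_grid(a, b) -> None:
    if a.box != b.box or not np.isclose(a.pixel_size, b.pixel_size):
        raise ValueError(
            f"grid mismatch: {a.box}px/{a.pixel_size}A vs {b.box}px/{b.pixel_size}A"
        )


def make_soft_mask(
    map_: VolumeGrid, threshold: float, extend_px: int = 3, soft_edge_px: int = 6
) -> SoftMask:
    """Binarize a map, dilate, and add a raised-cosine edge.

    The binary region is ``map >= threshold`` extended outward by
    ``extend_px`` (Euclidean distance).  Outside it, values fall from 1 to 0
    along ``0.5 (1 + cos(pi d / soft_edge_px))`` where ``d`` is the Euclidean
    distance to the extended region, so the value is exactly 0.5 halfway
    through the edge.
    """
    if extend_px < 0 or soft_edge_px < 0:
        raise ValueError("extend_px and soft_edge_px must be >= 0")
    binary = map_.data >= threshold
    if not binary.any():
        raise ValueError("empty mask: threshold above the map maximum")
    dist = ndimage.distance_transform_edt(~binary)
    if extend_px > 0:
        binary = dist <= extend_px
        dist = ndimage.distance_transform_edt(~binary)
    out = np.zeros(map_.data.shape)
    out[binary] = 1.0
    if soft_edge_px > 0:
        edge = (~binary) & (dist <= soft_edge_px)
        out[edge] = 0.5 * (1.0 + np.cos(np.pi * dist[edge] / soft_edge_px))
    return SoftMask(
        VolumeGrid(out, map_.pixel_size),
        threshold=threshold,
        extend_px=extend_px,
        soft_edge_px=soft_edge_px,
    )


def mask_subtract(whole: SoftMask, part: SoftMask) -> SoftMask:
    """Mask difference ``clip(whole - part, 0, 1)``.

    This is how the "everything else" mask is built: the mask of the entire
    complex minus the focus-region mask.
    """
    _check_same_grid(whole, part)
    data = np.clip(whole.data - part.data, 0.0, 1.0)
    return SoftMask(VolumeGrid(data, whole.pixel_size))


def apply_mask(vol: VolumeGrid, mask: SoftMask) -> VolumeGrid:
    """Voxelwise product of a map with a soft mask."""
    _check_same_grid(vol, mask)
    return VolumeGrid(vol.data * mask.data, vol.pixel_size)


def pseudo_atoms_to_map(
    centers, box: int, pixel_size: float
) -> VolumeGrid:
    """Render a list of Gaussian pseudo-atoms onto a cubic grid.

    ``centers`` rows are ``(x, y, z, radius, weight)`` in Angstrom, with
    coordinates relative to the box center.  Each atom is an isotropic
    Gaussian with ``sigma = radius / 2``.  A stand-in for atomic-model to
    density conversion when building focus masks around a modeled region.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 5)
    half = box / 2.0 * pixel_size
    data = np.zeros((box, box, box))
    if centers.size == 0:
        return VolumeGrid(data, pixel_size)
    if np.any(np.abs(centers[:, :3]) >= half):
        raise ValueError("pseudo-atom center outside the box")
    g = (np.arange(box) - box // 2) * pixel_size
    z, y, x = np.meshgrid(g, g, g, indexing="ij")
    for cx, cy, cz, radius, weight in centers:
        sigma = radius / 2.0
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        data += weight * np.exp(-r2 / (2.0 * sigma**2))
    return VolumeGrid(data, pixel_size)
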