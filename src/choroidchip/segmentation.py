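"""Seeded 3D watershed segmentation.

Seeds are intensity local maxima above a *seeds threshold* within a
configurable Chebyshev radius; the watershed then grows each seed outward by
a priority flood, claiming voxels in order of descending intensity but only
above an *image threshold*. For the red (cell tracker) channel both
thresholds are absolute; for the green (CD3) channel they are derived per
chip from the maximum green intensity via two fixed normalization constants,
which absorbs chip-to-chip staining variability.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .stack import ImageStack, LabelMap

__all__ = [
    "Seed",
    "WatershedParams",
    "GreenNormalization",
    "detect_seeds",
    "green_thresholds",
    "watershed3d",
    "binarize_labels",
    "GREEN_SEEDS_CONSTANT",
    "GREEN_IMAGE_CONSTANT",
]

#: Per-chip normalization constants for the green-channel thresholds
#: (threshold = constant × max green intensity of that chip).
GREEN_SEEDS_CONSTANT = 0.043574883
GREEN_IMAGE_CONSTANT = 0.021787442


@dataclass(frozen=True)
class Seed:
    """A seed voxel: ``position_vox`` is a (z, y, x) index."""

    position_vox: tuple[int, int, int]
    intensity: float


@dataclass
class WatershedParams:
    """Seed/flood parameters; red-channel defaults are the fixed published ones."""

    seed_radius_vox: int = 4
    seeds_threshold: float = 1000.0
    image_threshold: float = 500.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.seed_radius_vox < 1:
            raise ValueError("seed radius must be >= 1")
        if not (self.seeds_threshold >= self.image_threshold > 0):
            raise ValueError("require seeds_threshold >= image_threshold > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class GreenNormalization:
    """Green thresholds scale with the chip's maximum green intensity."""

    max_green: float
    seeds_constant: float = GREEN_SEEDS_CONSTANT
    image_constant: float = GREEN_IMAGE_CONSTANT

    def __post_init__(self) -> None:
        if self.seeds_constant <= 0 or self.image_constant <= 0:
            raise ValueError("normalization constants must be positive")


def green_thresholds(norm: GreenNormalization) -> tuple[float, float]:
    """Return (seeds_threshold, image_threshold) for one chip's green channel."""
    if norm.max_green <= 0:
        raise ValueError(f"max_green must be positive (blank chip?), got {norm.max_green}")
    return norm.seeds_constant * norm.max_green, norm.image_constant * norm.max_green


def detect_seeds(
    stack: ImageStack, radius_vox: int = 4, seeds_threshold: float = 1000.0
) -> list[Seed]:
    """Find local maxima above the seeds threshold.

    A voxel qualifies when its intensity is >= ``seeds_threshold`` and
    maximal over the Chebyshev ball (cube) of the given radius. A flat
    plateau of tied maxima yields a single seed at its lexicographically
    smallest (z, y, x) index; adjacent qualifying voxels necessarily share
    one intensity, so plateaus are the 26-connected components of the
    qualifying mask.
    """
    if radius_vox < 1:
        raise ValueError("radius must be >= 1")
    img = stack.voxels
    size = 2 * radius_vox + 1
    local_max = ndimage.maximum_filter(img, size=size, mode="reflect")
    candidates = (img == local_max) & (img >= seeds_threshold)
    if not candidates.any():
        return []
    lab, n = ndimage.label(candidates, structure=np.ones((3, 3, 3), dtype=bool))
    flat = lab.ravel()
    idx = np.flatnonzero(flat)
    # first occurrence in scan order per plateau = lexicographically smallest
    order = np.argsort(flat[idx], kind="stable")
    sorted_labels = flat[idx][order]
    first = np.searchsorted(sorted_labels, np.arange(1, n + 1), side="left")
    picks = idx[order][first]
    seeds = []
    for p in sorted(picks.tolist()):
        pos = np.unravel_index(p, img.shape)
        seeds.append(Seed(position_vox=tuple(int(v) for v in pos), intensity=float(img[pos])))
    return seeds


def _neighbor_offsets(connectivity: int):
    offsets = []
    for dz, dy, dx in product((-1, 0, 1), repeat=3):
        if dz == dy == dx == 0:
            continue
        order = abs(dz) + abs(dy) + abs(dx)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append((dz, dy, dx))
    return offsets


def watershed3d(
    stack: ImageStack,
    seeds: list[Seed],
    image_threshold: float,
    connectivity: int = 26,
) -> LabelMap:
    """Grow labels from seeds by priority flood.

    Voxels with intensity >= ``image_threshold`` are assigned, in order of
    descending intensity (ties broken first-in-first-out), to the label of
    the already-assigned neighbor that first reached them; voxels below the
    threshold, or with no assigned-neighbor path, stay background. Each seed
    keeps its own label (seed k in list order gets label k+1).
    """
    img = stack.voxels
    shape = img.shape
    for s in seeds:
        if img[s.position_vox] < image_threshold:
            raise ValueError(
                f"seed at {s.position_vox} has intensity {img[s.position_vox]} "
                f"below the image threshold {image_threshold}"
            )
    # Work on a 1-voxel pad so neighbor lookups need no bounds checks: padded
    # border voxels carry label -1 (never background) and intensity below any
    # threshold, so they are neither claimed nor enqueued.
    pad = np.pad(img.astype(np.float64), 1, mode="constant", constant_values=-np.inf)
    pnz, pny, pnx = pad.shape
    intens = pad.ravel().tolist()
    lab_flat = [0] * (pnz * pny * pnx)
    border = np.zeros(pad.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    for i in np.flatnonzero(border.ravel()).tolist():
        lab_flat[i] = -1
    stride_z = pny * pnx
    flat_offsets = [
        dz * stride_z + dy * pnx + dx for dz, dy, dx in _neighbor_offsets(connectivity)
    ]

    def flat_index(pos):
        z, y, x = pos
        return (z + 1) * stride_z + (y + 1) * pnx + (x + 1)

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for k, s in enumerate(seeds, start=1):
        lab_flat[flat_index(s.position_vox)] = k
    push = heapq.heappush
    pop = heapq.heappop
    for k, s in enumerate(seeds, start=1):
        i0 = flat_index(s.position_vox)
        for off in flat_offsets:
            j = i0 + off
            if lab_flat[j] == 0 and intens[j] >= image_threshold:
                push(heap, (-intens[j], counter, j, k))
                counter += 1
    while heap:
        _, _, i, k = pop(heap)
        if lab_flat[i] != 0:
            continue
        lab_flat[i] = k
        for off in flat_offsets:
            j = i + off
            if lab_flat[j] == 0 and intens[j] >= image_threshold:
                push(heap, (-intens[j], counter, j, k))
                counter += 1
    labels = np.asarray(lab_flat, dtype=np.int32).reshape(pad.shape)[1:-1, 1:-1, 1:-1]
    return LabelMap(labels=np.ascontiguousarray(labels), spacing_xyz=stack.spacing_xyz)


def binarize_labels(labels: LabelMap) -> ImageStack:
    """Map every positive label to 255 and background to 0."""
    out = np.where(labels.labels > 0, 255, 0).astype(np.uint8)
    return ImageStack(voxels=out, spacing_xyz=labels.spacing_xyz, channel="binary")
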