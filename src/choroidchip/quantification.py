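"""Object measurement, size filtering, T-cell classification and
depth-stratified recruitment counts.

After watershed segmentation, every red (cell-tracker) object is measured
(3D centroid in µm and volume in voxels and µm³), objects smaller than 30
voxels are discarded, and each remaining PBMC is classified as a T cell when
it shares at least one voxel with the binarized green (CD3) segmentation.
Counts are finally split between the bottom (0–63 µm) and top (64–126 µm)
halves of the imaged melanocyte compartment.

The module also carries the melanocyte seeding-density calculation: given a
target volume fraction of the stromal channel, the mean suspended-cell
diameter and a spreading expansion factor, it returns the cell concentration
to seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .stack import ImageStack, LabelMap

__all__ = [
    "CellObject",
    "CompartmentBins",
    "RecruitmentReport",
    "SeedingSpec",
    "measure_objects",
    "size_filter",
    "classify_tcells",
    "bin_by_depth",
    "seeding_concentration",
    "MIN_OBJECT_VOXELS",
    "UM3_PER_UL",
]

logger = logging.getLogger(__name__)

#: Objects smaller than this many voxels are eliminated by the size filter.
MIN_OBJECT_VOXELS = 30

#: Exact unit conversion: 1 µL = 1e9 µm³.
UM3_PER_UL = 1.0e9


@dataclass
class CellObject:
    """One segmented object. ``centroid_um`` is (x, y, z) with z measured
    from the bottom of the imaged compartment (z = 0)."""

    label: int
    centroid_um: tuple[float, float, float]
    volume_vox: int
    volume_um3: float
    is_tcell: bool = False


@dataclass
class CompartmentBins:
    """Bottom/top depth halves of the melanocyte compartment in µm."""

    bottom_range_um: tuple[float, float] = (0.0, 63.0)
    top_range_um: tuple[float, float] = (64.0, 126.0)

    def __post_init__(self) -> None:
        b0, b1 = self.bottom_range_um
        t0, t1 = self.top_range_um
        if not (b0 < b1 <= t0 < t1):
            raise ValueError("bins must be disjoint and ordered bottom < top")

    @property
    def split_um(self) -> float:
        """Centroids at or below this depth count as bottom."""
        return self.bottom_range_um[1]

    @property
    def depth_um(self) -> float:
        return self.top_range_um[1]


@dataclass
class RecruitmentReport:
    """Per-chip recruitment counts; T cells are a subset of PBMCs."""

    chip_id: str
    n_pbmc_total: int
    n_pbmc_top: int
    n_pbmc_bottom: int
    n_tcell_total: int
    n_tcell_top: int
    n_tcell_bottom: int
    params_digest: str = ""

    def __post_init__(self) -> None:
        if self.n_pbmc_total != self.n_pbmc_top + self.n_pbmc_bottom:
            raise ValueError("PBMC total must equal top + bottom")
        if self.n_tcell_total != self.n_tcell_top + self.n_tcell_bottom:
            raise ValueError("T-cell total must equal top + bottom")
        for t, p in (
            (self.n_tcell_total, self.n_pbmc_total),
            (self.n_tcell_top, self.n_pbmc_top),
            (self.n_tcell_bottom, self.n_pbmc_bottom),
        ):
            if t > p:
                raise ValueError("T cells must be a subset of PBMCs")

    def as_dict(self) -> dict:
        return {
            "chip_id": self.chip_id,
            "n_pbmc_total": self.n_pbmc_total,
            "n_pbmc_top": self.n_pbmc_top,
            "n_pbmc_bottom": self.n_pbmc_bottom,
            "n_tcell_total": self.n_tcell_total,
            "n_tcell_top": self.n_tcell_top,
            "n_tcell_bottom": self.n_tcell_bottom,
            "params_digest": self.params_digest,
        }


@dataclass
class SeedingSpec:
    """Inputs of the melanocyte seeding-density calculation.

    ``expansion_factor`` scales the suspended (spherical) cell volume to
    account for the morphology change while spreading in the hydrogel.
    """

    cell_diameter_um: float = 28.5
    target_fraction: float = 0.05
    channel_volume_ul: float = 1.5
    seeding_volume_ul: float = 5.0
    expansion_factor: float = 3.68

    def __post_init__(self) -> None:
        if self.cell_diameter_um <= 0:
            raise ValueError("cell diameter must be positive")
        if not 0.0 <= self.target_fraction < 1.0:
            raise ValueError("target fraction must be in [0, 1)")
        if self.channel_volume_ul <= 0 or self.seeding_volume_ul <= 0:
            raise ValueError("volumes must be positive")
        if self.expansion_factor <= 0:
            raise ValueError("expansion factor must be positive")


def measure_objects(labels: LabelMap) -> list[CellObject]:
    """Measure centroid (µm) and volume (voxels, µm³) of every labelled object.

    The centroid is the unweighted mean of member-voxel centers; voxel i
    along an axis sits at ``i * spacing`` for that axis. Volumes use the
    full voxel-volume product, so a warning is emitted when the spacing is
    not cubic (the published volumes assume cubic voxels).
    """
    sx, sy, sz = labels.spacing_xyz
    if not (math.isclose(sx, sy, rel_tol=0.02) and math.isclose(sx, sz, rel_tol=0.02)):
        warnings.warn(
            f"non-cubic voxel spacing {labels.spacing_xyz}; volumes use the "
            "voxel-volume product",
            stacklevel=2,
        )
    n = labels.n_objects
    if n == 0:
        return []
    lab = labels.labels
    index = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(lab, dtype=np.int64), lab, index)
    centers = ndimage.center_of_mass(np.ones(lab.shape), lab, index)
    objects = []
    for k, cnt, (cz, cy, cx) in zip(index, counts, centers):
        objects.append(
            CellObject(
                label=int(k),
                centroid_um=(cx * sx, cy * sy, cz * sz),
                volume_vox=int(cnt),
                volume_um3=float(cnt) * sx * sy * sz,
                is_tcell=False,
            )
        )
    return objects


def size_filter(objects: list[CellObject], min_vox: int = MIN_OBJECT_VOXELS) -> list[CellObject]:
    """Drop objects strictly smaller than ``min_vox`` voxels; order preserved."""
    if min_vox < 0:
        raise ValueError("min_vox must be >= 0")
    return [o for o in objects if o.volume_vox >= min_vox]


def classify_tcells(
    red_objects: list[CellObject], red_labels: LabelMap, green_binary: ImageStack
) -> list[CellObject]:
    """Flag a red object as a T cell when it overlaps >= 1 green object voxel.

    ``green_binary`` is the binarized green label map (255 on object voxels);
    overlap is measured as the maximum green value within the object's red
    label, so any single shared voxel (green value > 0) suffices.
    """
    if red_labels.shape_zyx != green_binary.shape_zyx:
        raise ValueError(
            f"shape mismatch: red labels {red_labels.shape_zyx} vs "
            f"green {green_binary.shape_zyx}"
        )
    if not red_objects:
        return []
    index = [o.label for o in red_objects]
    max_green = ndimage.labeled_comprehension(
        green_binary.voxels, red_labels.labels, index, np.max, float, 0.0
    )
    return [replace(o, is_tcell=bool(g > 0)) for o, g in zip(red_objects, np.atleast_1d(max_green))]


def bin_by_depth(
    objects: list[CellObject],
    bins: CompartmentBins = None,
    chip_id: str = "",
    params_digest: str = "",
) -> RecruitmentReport:
    """Split counts into bottom/top compartment halves by centroid depth.

    An object is bottom iff its centroid z <= the upper edge of the bottom
    range; anything above, including centroids beyond the nominal analyzed
    depth (which are logged), counts as top.
    """
    bins = bins or CompartmentBins()
    n_bottom = n_top = t_bottom = t_top = 0
    for o in objects:
        z = o.centroid_um[2]
        if z > bins.depth_um or z < bins.bottom_range_um[0]:
            logger.warning(
                "object %d centroid z=%.2f um outside the analyzed depth "
                "[%.1f, %.1f]; counted in the nearest bin",
                o.label, z, bins.bottom_range_um[0], bins.depth_um,
            )
        if z <= bins.split_um:
            n_bottom += 1
            t_bottom += int(o.is_tcell)
        else:
            n_top += 1
            t_top += int(o.is_tcell)
    return RecruitmentReport(
        chip_id=chip_id,
        n_pbmc_total=n_bottom + n_top,
        n_pbmc_top=n_top,
        n_pbmc_bottom=n_bottom,
        n_tcell_total=t_bottom + t_top,
        n_tcell_top=t_top,
        n_tcell_bottom=t_bottom,
        params_digest=params_digest,
    )


def seeding_concentration(spec: SeedingSpec) -> dict:
    """Melanocyte numbers needed to reach a target stromal volume fraction.

    The suspended cell is modelled as a sphere of the given diameter; its
    effective in-gel volume is that sphere volume times the expansion
    factor. The required in-channel cell number is the target fraction of
    the channel volume divided by the expanded single-cell volume; the
    seeding suspension must carry that number per channel volume, and the
    total prepared cells follow from the seeding volume.
    """
    sphere_um3 = math.pi / 6.0 * spec.cell_diameter_um**3
    expanded_um3 = sphere_um3 * spec.expansion_factor
    channel_um3 = spec.channel_volume_ul * UM3_PER_UL
    cells_in_channel = spec.target_fraction * channel_um3 / expanded_um3
    cells_per_ul = cells_in_channel / spec.channel_volume_ul
    return {
        "single_cell_volume_um3": sphere_um3,
        "expanded_cell_volume_um3": expanded_um3,
        "cells_in_channel": cells_in_channel,
        "cells_per_ul": cells_per_ul,
        "total_cells_in_seeding_volume": cells_per_ul * spec.seeding_volume_ul,
    }
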