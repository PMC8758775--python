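"""In-memory containers for 3D microscopy data.

An :class:`ImageStack` is a single-channel 3D voxel grid with physical
spacing; it is the unit every filter and the watershed consume and produce.
Arrays are stored in ``(z, y, x)`` axis order (the order TIFF z-stacks are
read in), while physical spacing is reported in ``(x, y, z)`` order in µm,
matching how microscope metadata states it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["ImageStack", "LabelMap"]


@dataclass
class ImageStack:
    """A 3D single-channel image with voxel spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(nz, ny, nx)`` with non-negative intensities.
    spacing_xyz
        Physical voxel spacing ``(sx, sy, sz)`` in µm; anisotropy allowed.
    channel
        Free-text channel tag (e.g. ``"red"``, ``"green"``).
    """

    voxels: np.ndarray
    spacing_xyz: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        self.spacing_xyz = tuple(float(s) for s in self.spacing_xyz)
        if len(self.spacing_xyz) != 3 or any(s <= 0 for s in self.spacing_xyz):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_xyz}")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing_xyz
        return sx * sy * sz

    def is_cubic(self, rel_tol: float = 0.02) -> bool:
        sx, sy, sz = self.spacing_xyz
        return abs(sy - sx) <= rel_tol * sx and abs(sz - sx) <= rel_tol * sx

    @property
    def depth_um(self) -> float:
        """Physical depth spanned by the z slice *centers* (first center at z=0)."""
        return (self.voxels.shape[0] - 1) * self.spacing_xyz[2]

    def with_voxels(self, voxels: np.ndarray, spacing_xyz=None) -> "ImageStack":
        return ImageStack(
            voxels=voxels,
            spacing_xyz=self.spacing_xyz if spacing_xyz is None else spacing_xyz,
            channel=self.channel,
        )

    # ---- TIFF I/O -----------------------------------------------------

    def save_tiff(self, path) -> None:
        """Write as an ImageJ-style TIFF with spacing metadata."""
        data = self.voxels
        if data.dtype not in (np.uint8, np.uint16, np.float32):
            data = data.astype(np.float32)
        sx, sy, sz = self.spacing_xyz
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )

    @classmethod
    def from_tiff(cls, path, channel: str = "") -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            if data.ndim == 2:
                data = data[None]
            sz = 1.0
            if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
                sz = float(tf.imagej_metadata["spacing"])
            page = tf.pages[0]
            sx = sy = 1.0
            if "XResolution" in page.tags:
                num, den = page.tags["XResolution"].value
                if num:
                    sx = den / num
            if "YResolution" in page.tags:
                num, den = page.tags["YResolution"].value
                if num:
                    sy = den / num
        return cls(voxels=data, spacing_xyz=(sx, sy, sz), channel=channel)


@dataclass
class LabelMap:
    """Integer-labelled 3D grid: 0 = background, k > 0 = object k.

    Labels are expected to be the contiguous set ``{0..n_objects}``.
    """

    labels: np.ndarray
    spacing_xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing_xyz = tuple(float(s) for s in self.spacing_xyz)
        if any(s <= 0 for s in self.spacing_xyz):
            raise ValueError("spacing must be positive")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.labels.shape

    def save_tiff(self, path) -> None:
        data = self.labels
        dtype = np.uint16 if self.n_objects < 2**16 else np.uint32
        sx, sy, sz = self.spacing_xyz
        tifffile.imwrite(
            str(path),
            data.astype(dtype),
            imagej=(dtype == np.uint16),
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
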