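"""Brute-force reference implementations used only by the tests.

Everything here trades efficiency for obviousness: explicit loops over
voxels, explicit boundary reflection, explicit frontier scans. These
oracles are kept independent of the package code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Map an out-of-range index to its 'reflect' (half-sample) mirror."""
    if n == 1:
        return 0
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def sphere_voxel_count(shape_zyx, spacing_xyz, center_um, radius_um) -> int:
    """Count voxels whose center lies inside the analytic sphere."""
    nz, ny, nx = shape_zyx
    sx, sy, sz = spacing_xyz
    cx, cy, cz = center_um
    count = 0
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                d2 = (ix * sx - cx) ** 2 + (iy * sy - cy) ** 2 + (iz * sz - cz) ** 2
                if d2 <= radius_um**2:
                    count += 1
    return count


def gaussian_kernel_1d(sigma: float, truncate: float = 3.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur_oracle(img: np.ndarray, sigma: float, truncate: float = 3.0) -> np.ndarray:
    """Dense 3D convolution with a separable sampled-Gaussian kernel and
    reflective borders, evaluated voxel by voxel."""
    k1 = gaussian_kernel_1d(sigma, truncate)
    r = (len(k1) - 1) // 2
    nz, ny, nx = img.shape
    out = np.zeros_like(img, dtype=np.float64)
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                acc = 0.0
                for dz in range(-r, r + 1):
                    wz = k1[dz + r]
                    z = reflect_index(iz + dz, nz)
                    for dy in range(-r, r + 1):
                        wy = k1[dy + r]
                        y = reflect_index(iy + dy, ny)
                        row = img[z, y]
                        for dx in range(-r, r + 1):
                            acc += wz * wy * k1[dx + r] * row[reflect_index(ix + dx, nx)]
                out[iz, iy, ix] = acc
    return out


def unsharp_oracle(img: np.ndarray, sigma: float, repeats: int, truncate: float = 3.0):
    out = np.asarray(img, dtype=np.float64)
    for _ in range(repeats):
        out = np.maximum(out - gaussian_blur_oracle(out, sigma, truncate), 0.0)
    return out


def hybrid_median_oracle(img: np.ndarray) -> np.ndarray:
    """Median of {in-plane 3x3 median, 3D-diagonal median, center}."""
    nz, ny, nx = img.shape
    out = np.zeros_like(img, dtype=np.float64)
    diag_offsets = [(dz, dy, dx) for dz in (-1, 1) for dy in (-1, 1) for dx in (-1, 1)]
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                planar = [
                    img[iz, reflect_index(iy + dy, ny), reflect_index(ix + dx, nx)]
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                ]
                diag = [
                    img[reflect_index(iz + dz, nz), reflect_index(iy + dy, ny),
                        reflect_index(ix + dx, nx)]
                    for dz, dy, dx in diag_offsets
                ] + [img[iz, iy, ix]]
                three = sorted(
                    [float(np.median(planar)), float(np.median(diag)), float(img[iz, iy, ix])]
                )
                out[iz, iy, ix] = three[1]
    return out


def ball_offsets(radius: int):
    offs = []
    for dz in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dz * dz + dy * dy + dx * dx <= radius * radius:
                    offs.append((dz, dy, dx))
    return offs


def grey_closing_oracle(img: np.ndarray, radius: int) -> np.ndarray:
    """Set-by-set grayscale dilation then erosion with a discrete ball."""
    offs = ball_offsets(radius)
    nz, ny, nx = img.shape

    def _apply(src, fn):
        dst = np.zeros_like(src, dtype=np.float64)
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    vals = [
                        src[reflect_index(iz + dz, nz), reflect_index(iy + dy, ny),
                            reflect_index(ix + dx, nx)]
                        for dz, dy, dx in offs
                    ]
                    dst[iz, iy, ix] = fn(vals)
        return dst

    return _apply(_apply(np.asarray(img, dtype=np.float64), max), min)


def local_maxima_oracle(img: np.ndarray, radius: int, threshold: float):
    """All (z, y, x) seeds per the plateau rule, by exhaustive window scans."""
    nz, ny, nx = img.shape
    candidate = np.zeros(img.shape, dtype=bool)
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                v = img[iz, iy, ix]
                if v < threshold:
                    continue
                window_max = -math.inf
                for dz in range(-radius, radius + 1):
                    z = iz + dz
                    if not 0 <= z < nz:
                        continue
                    for dy in range(-radius, radius + 1):
                        y = iy + dy
                        if not 0 <= y < ny:
                            continue
                        for dx in range(-radius, radius + 1):
                            x = ix + dx
                            if 0 <= x < nx:
                                window_max = max(window_max, img[z, y, x])
                if v >= window_max:
                    candidate[iz, iy, ix] = True
    # group tied candidates into 26-connected plateaus; keep smallest index
    seen = np.zeros(img.shape, dtype=bool)
    seeds = []
    for pos in sorted(map(tuple, np.argwhere(candidate))):
        if seen[pos]:
            continue
        stack = [pos]
        members = []
        seen[pos] = True
        while stack:
            cz, cy, cx = stack.pop()
            members.append((cz, cy, cx))
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        q = (cz + dz, cy + dy, cx + dx)
                        if (
                            0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx
                            and candidate[q] and not seen[q]
                        ):
                            seen[q] = True
                            stack.append(q)
        seeds.append(min(members))
    return sorted(seeds)


def watershed_oracle(img: np.ndarray, seed_positions, image_threshold: float) -> np.ndarray:
    """Priority flood by repeated scans of an append-only frontier list.

    The frontier holds (voxel, label) records in enqueue order; each step
    assigns the unassigned frontier voxel with the highest intensity
    (earliest enqueue on ties) to the label that enqueued it, then appends
    that voxel's unassigned above-threshold neighbors.
    """
    nz, ny, nx = img.shape
    labels = np.zeros(img.shape, dtype=np.int32)
    neighbors = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]

    def in_bounds(p):
        return 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx

    frontier: list[tuple[tuple, int]] = []
    for k, pos in enumerate(seed_positions, start=1):
        labels[pos] = k
    for k, pos in enumerate(seed_positions, start=1):
        for d in neighbors:
            q = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
            if in_bounds(q) and labels[q] == 0 and img[q] >= image_threshold:
                frontier.append((q, k))
    while True:
        best = None
        for idx, (q, k) in enumerate(frontier):
            if labels[q] != 0:
                continue
            if best is None or img[q] > img[frontier[best][0]]:
                best = idx
        if best is None:
            break
        q, k = frontier[best]
        del frontier[best]
        labels[q] = k
        for d in neighbors:
            p = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            if in_bounds(p) and labels[p] == 0 and img[p] >= image_threshold:
                frontier.append((p, k))
    return labels
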