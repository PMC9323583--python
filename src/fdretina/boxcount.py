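"""Box-counting fractal dimension estimation.

The skeleton map is overlaid with a single grid of s x s cells anchored at
the top-left corner (partial cells at the right/bottom edges count as
cells).  Occupied cells are counted for a strictly decreasing dyadic
schedule of mesh sizes, and the fractal dimension is the ordinary
least-squares slope of log(count) against log(1/size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, ProcessingError
from .preprocess import (
    DEFAULT_THRESHOLD,
    SkeletonMap,
    _as_pixels,
    binarise,
    skeletonise,
    verify_continuity,
)

MIN_SCALES = 4


@dataclass
class MeshSchedule:
    """Strictly decreasing mesh sizes in pixels."""

    sizes_px: list[int]

    def __post_init__(self) -> None:
        sizes = [int(s) for s in self.sizes_px]
        if any(s < 1 for s in sizes):
            raise InputError("mesh sizes must be positive")
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise InputError("mesh sizes must be strictly decreasing")
        self.sizes_px = sizes


@dataclass
class BoxCountCurve:
    """Paired (mesh size, occupied-box count) series."""

    sizes_px: list[int]
    counts: list[int]


@dataclass
class FDResult:
    fd: float
    intercept: float
    r_squared: float
    n_scales: int


def mesh_schedule(image_height: int, image_width: int) -> MeshSchedule:
    """Dyadic mesh sizes: largest power of 2 <= min(H, W)/2, halving to 2."""
    m = min(int(image_height), int(image_width))
    if m < 16:
        raise InputError(f"image too small for box counting (min dim {m} < 16)")
    top = 1 << int(np.floor(np.log2(m / 2)))
    sizes = []
    s = top
    while s >= 2:
        sizes.append(s)
        s //= 2
    return MeshSchedule(sizes_px=sizes)


def _count_occupied(mask: np.ndarray, size: int) -> int:
    h, w = mask.shape
    nh = -(-h // size)
    nw = -(-w // size)
    padded = np.zeros((nh * size, nw * size), dtype=bool)
    padded[:h, :w] = mask
    blocks = padded.reshape(nh, size, nw, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_curve(skeleton, schedule: MeshSchedule) -> BoxCountCurve:
    """Count occupied grid cells for every mesh size in the schedule."""
    pixels = skeleton.pixels if isinstance(skeleton, SkeletonMap) else skeleton
    mask = np.asarray(pixels).astype(bool)
    if mask.ndim != 2:
        raise InputError("skeleton must be a 2D grid")
    if not mask.any():
        raise InputError("empty structure: skeleton has no foreground pixels")
    if schedule.sizes_px and schedule.sizes_px[0] > min(mask.shape):
        raise InputError("largest mesh size exceeds image dimensions")
    counts = [_count_occupied(mask, s) for s in schedule.sizes_px]
    return BoxCountCurve(sizes_px=list(schedule.sizes_px), counts=counts)


def fit_fd(curve: BoxCountCurve) -> FDResult:
    """OLS fit of log(count) vs log(1/size); the slope is the FD."""
    sizes = np.asarray(curve.sizes_px, dtype=float)
    counts = np.asarray(curve.counts, dtype=float)
    if sizes.size != counts.size:
        raise InputError("curve sizes and counts differ in length")
    if sizes.size < MIN_SCALES:
        raise InputError(
            f"need at least {MIN_SCALES} scales to fit, got {sizes.size}")
    if (counts < 1).any():
        raise InputError("all box counts must be >= 1")
    x = np.log(1.0 / sizes)
    y = np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # flat log-log line: perfect fit of a zero slope
        r_squared = 1.0
    else:
        r_squared = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return FDResult(fd=float(slope), intercept=float(intercept),
                    r_squared=r_squared, n_scales=int(sizes.size))


def estimate_fd(image, threshold: float = DEFAULT_THRESHOLD,
                schedule: MeshSchedule | None = None) -> FDResult:
    """Full estimation: binarise -> skeletonise -> continuity -> box counts -> fit.

    Raises ProcessingError if thinning increases the 8-connected component
    count (the continuity requirement).
    """
    pixels = _as_pixels(image)
    binary = binarise(pixels, threshold)
    skeleton = skeletonise(binary)
    report = verify_continuity(binary, skeleton)
    if not report.passed:
        raise ProcessingError(
            "continuity check failed: skeleton has "
            f"{report.n_components_skeleton} components vs "
            f"{report.n_components_binary} in the binary map")
    if schedule is None:
        schedule = mesh_schedule(*pixels.shape)
    curve = box_count_curve(skeleton, schedule)
    return fit_fd(curve)
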