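"""Binarisation and skeletonisation of en-face angiogram images.

A grayscale image is reduced to a one-pixel-thick vessel centreline map in
two deterministic steps: a fixed-threshold binarisation (pixel >= threshold
maps to foreground) followed by iterative morphological thinning.  A
continuity report compares 8-connected component counts before and after
thinning so that skeletonisation can be rejected if it fragments the
vessel structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.measure import label
from skimage.morphology import thin

from .errors import ConfigurationError, InputError

DEFAULT_THRESHOLD = 0.5


@dataclass
class EnFaceImage:
    """A 2D grayscale intensity grid with acquisition metadata.

    Intensities must lie in [0, 1]; rows are indexed top to bottom
    (row-major, origin top-left, 0-based).
    """

    pixels: np.ndarray
    participant_id: Optional[str] = None
    observer_id: Optional[int] = None
    scan_index: Optional[int] = None
    plexus: Optional[str] = None  # "SCP" | "DCP"
    eye: Optional[str] = None  # "right" | "left"
    pixel_pitch_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("image must be a non-empty 2D grid")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InputError("image intensities must lie in [0, 1]")


@dataclass
class BinaryMap:
    """Binary vessel mask plus the threshold that produced it."""

    pixels: np.ndarray
    threshold_used: float


@dataclass
class SkeletonMap:
    """One-pixel-thick binary map: no 2x2 block is fully foreground."""

    pixels: np.ndarray


@dataclass
class ContinuityReport:
    n_components_binary: int
    n_components_skeleton: int
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = self.n_components_skeleton <= self.n_components_binary


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, EnFaceImage):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise InputError("image must be a non-empty 2D grid")
    return arr


def binarise(image, threshold: float = DEFAULT_THRESHOLD) -> BinaryMap:
    """Threshold an image: pixel >= threshold becomes foreground (1).

    The >= tie-break is part of the contract so results are bit-exact.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    pixels = _as_pixels(image)
    return BinaryMap(pixels=(pixels >= threshold).astype(np.uint8),
                     threshold_used=float(threshold))


def _is_simple(window: np.ndarray) -> bool:
    """True if deleting the centre of a 3x3 foreground window preserves
    local topology (8-connectivity foreground / 4-connectivity background)."""
    fg = window.copy()
    fg[1, 1] = False
    if not fg.any():
        return False  # isolated pixel: deletion removes a component
    if label(fg, connectivity=2).max() != 1:
        return False
    # deletion must not open or close a hole: the centre needs a background
    # 4-neighbour, all in one 4-connected background component
    bg = ~window
    bg[1, 1] = True
    four = [(0, 1), (1, 0), (1, 2), (2, 1)]
    if not any(bg[r, c] for r, c in four if (r, c) != (1, 1)):
        return False
    bg_lab = label(bg, connectivity=1)
    touching = {bg_lab[r, c] for r, c in four if bg_lab[r, c] > 0}
    return len(touching) == 1


def _prune_thick_blocks(skel: np.ndarray) -> np.ndarray:
    """Delete simple pixels until no 2x2 block is fully foreground.

    Junctions of diagonal strokes can survive morphological thinning as
    2x2 clumps; each deletion here is topology-preserving, so component
    counts are unchanged.
    """
    a = np.pad(skel.astype(bool), 1)
    changed = True
    while changed:
        blocks = a[:-1, :-1] & a[1:, :-1] & a[:-1, 1:] & a[1:, 1:]
        if not blocks.any():
            return a[1:-1, 1:-1]
        changed = False
        for r, c in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if a[rr, cc] and _is_simple(a[rr - 1:rr + 2, cc - 1:cc + 2]):
                    a[rr, cc] = False
                    changed = True
                    break
    # residual blocks are X-crossings where no pixel is locally simple;
    # delete a pixel anyway when the global component count is preserved
    # (the severed arm almost always reconnects through the network)
    n_components = label(a, connectivity=2).max()
    changed = True
    while changed:
        blocks = a[:-1, :-1] & a[1:, :-1] & a[:-1, 1:] & a[1:, 1:]
        if not blocks.any():
            break
        changed = False
        for r, c in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if not a[rr, cc]:
                    continue
                a[rr, cc] = False
                if label(a, connectivity=2).max() <= n_components:
                    changed = True
                    break
                a[rr, cc] = True
            if changed:
                break
    return a[1:-1, 1:-1]


def skeletonise(binary: BinaryMap) -> SkeletonMap:
    """Thin a binary mask to one-pixel-wide centrelines.

    Uses iterative morphological thinning that preserves 8-connectivity,
    followed by a topology-preserving prune of any residual 2x2 clumps:
    the output foreground is a subset of the input foreground, contains no
    fully-foreground 2x2 block, and never has more 8-connected components
    than the input.  An empty mask yields an empty skeleton.
    """
    mask = np.asarray(binary.pixels).astype(bool)
    if mask.size == 0:
        raise InputError("binary map must be non-empty")
    skel = thin(mask)
    if has_full_2x2_block(skel):
        skel = _prune_thick_blocks(skel)
    return SkeletonMap(pixels=skel.astype(np.uint8))


def count_components(pixels: np.ndarray) -> int:
    """Number of 8-connected foreground components."""
    return int(label(np.asarray(pixels).astype(bool), connectivity=2).max())


def verify_continuity(binary: BinaryMap, skeleton: SkeletonMap) -> ContinuityReport:
    """Check that thinning did not fragment the vessel structure."""
    b = np.asarray(binary.pixels)
    s = np.asarray(skeleton.pixels)
    if b.shape != s.shape:
        raise InputError(
            f"dimension mismatch: binary {b.shape} vs skeleton {s.shape}")
    return ContinuityReport(
        n_components_binary=count_components(b),
        n_components_skeleton=count_components(s),
    )


def has_full_2x2_block(pixels: np.ndarray) -> bool:
    """True if any 2x2 window is fully foreground (thickness violation)."""
    a = np.asarray(pixels).astype(bool)
    if a.shape[0] < 2 or a.shape[1] < 2:
        return False
    return bool((a[:-1, :-1] & a[1:, :-1] & a[:-1, 1:] & a[1:, 1:]).any())
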