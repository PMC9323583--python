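"""Synthetic inputs for the pipeline: analytic fixtures, stochastic vessel
trees, repeat-scan perturbations, and variance-components tables.

All generators are bit-reproducible given (params, seed).  The fixtures
have closed-form pixel counts and box counts (line, filled square, single
pixel, Sierpinski triangle via Pascal's triangle mod 2 on a dyadic grid),
which makes them exact oracles for the box-counting estimator.  The vessel
tree is a recursive stochastic bifurcation process with decaying width and
jittered angles, rendered with distance-based anti-aliased strokes, and is
calibrated so the skeleton's box-counting dimension falls in the range
observed for dense retinal capillary networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, GenerationError

FIXTURE_NAMES = ("line", "filled_square", "single_pixel", "sierpinski")


@dataclass
class FixtureSpec:
    name: str
    size_px: int
    depth: int = 0

    def __post_init__(self) -> None:
        if self.name not in FIXTURE_NAMES:
            raise ConfigurationError(f"unknown fixture {self.name!r}")
        if self.size_px < 1:
            raise ConfigurationError("size_px must be positive")
        if self.name == "sierpinski" and self.size_px != 2 ** self.depth:
            raise ConfigurationError(
                f"sierpinski requires size_px == 2**depth "
                f"({self.size_px} != 2**{self.depth})")


@dataclass
class VesselTreeParams:
    """Parameters of the stochastic branching vessel generator.

    Defaults are the calibrated dense configuration: 256 px canvas with a
    skeleton FD landing in roughly [1.5, 1.8] across seeds.
    """

    size_px: int = 256
    n_roots: int = 6
    branch_prob: float = 0.3
    angle_jitter_deg: float = 22.0
    initial_width_px: float = 3.0
    width_decay: float = 0.93
    min_segment_px: int = 6
    max_segment_px: int = 14
    max_depth: int = 25
    background_noise_sd: float = 0.04
    vessel_intensity: float = 0.9
    max_segments: int = 1200  # hard cap, keeps generation bounded

    def validate(self) -> None:
        if self.size_px < 16:
            raise ConfigurationError("size_px must be >= 16")
        if self.n_roots < 1:
            raise ConfigurationError("n_roots must be positive")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ConfigurationError("branch_prob must be a probability")
        if not 0.0 < self.width_decay <= 1.0:
            raise ConfigurationError("width_decay must be in (0, 1]")
        if self.min_segment_px > self.max_segment_px:
            raise ConfigurationError("min_segment_px must be <= max_segment_px")
        if self.min_segment_px < 1:
            raise ConfigurationError("segment lengths must be positive")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be positive")
        if not 0.0 < self.vessel_intensity <= 1.0:
            raise ConfigurationError("vessel_intensity must be in (0, 1]")
        if not 0.0 <= self.background_noise_sd <= 1.0:
            raise ConfigurationError("background_noise_sd must be in [0, 1]")


@dataclass
class ScanPerturbation:
    """Repeat-scan perturbation: sub-pixel shift, contrast change, noise.

    The identity perturbation (zero shift, gamma 1, no extra noise, no
    reseed) maps any image to a pixel-identical copy.
    """

    shift_px: tuple[float, float] = (0.0, 0.0)  # (dx, dy)
    noise_reseed: bool = False
    gamma: float = 1.0
    extra_noise_sd: float = 0.0

    def validate(self) -> None:
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be > 0")
        if self.extra_noise_sd < 0:
            raise ConfigurationError("extra_noise_sd must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.shift_px == (0.0, 0.0) and self.gamma == 1.0
                and self.extra_noise_sd == 0.0 and not self.noise_reseed)

    def magnitude(self) -> float:
        """Scalar ordering proxy: shift norm + noise + contrast deviation."""
        dx, dy = self.shift_px
        return float(np.hypot(dx, dy) + 10 * self.extra_noise_sd
                     + abs(np.log(self.gamma)))


@dataclass
class VarianceComponentsParams:
    mu: float
    sigma_subject: float
    sigma_observer: float
    sigma_error: float
    n_subjects: int
    n_raters: int
    seed: int = 0

    def validate(self) -> None:
        if min(self.sigma_subject, self.sigma_observer, self.sigma_error) < 0:
            raise ConfigurationError("all sigmas must be >= 0")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_raters < 2:
            raise ConfigurationError("n_raters must be >= 2")

    @property
    def true_icc(self) -> float:
        total = (self.sigma_subject ** 2 + self.sigma_observer ** 2
                 + self.sigma_error ** 2)
        if total == 0:
            return 1.0
        return self.sigma_subject ** 2 / total


# ---------------------------------------------------------------------------
# fixtures


def generate_fixture(spec: FixtureSpec) -> np.ndarray:
    """Deterministic binary oracle image (uint8, values {0, 1})."""
    n = spec.size_px
    img = np.zeros((n, n), dtype=np.uint8)
    if spec.name == "line":
        img[n // 2, :] = 1
    elif spec.name == "filled_square":
        img[:, :] = 1
    elif spec.name == "single_pixel":
        img[0, 0] = 1
    elif spec.name == "sierpinski":
        # Pascal's triangle mod 2: cell (i, j) is set iff i & j == 0,
        # giving 3**depth foreground pixels on a 2**depth grid with exact
        # dyadic self-similarity.
        i = np.arange(n)
        img = ((i[:, None] & i[None, :]) == 0).astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# vessel trees


def _render_segment(canvas: np.ndarray, p0, p1, width: float,
                    intensity: float) -> None:
    """Stamp an anti-aliased stroke of the given width onto the canvas."""
    n = canvas.shape[0]
    half = width / 2.0 + 1.0
    r0 = max(int(np.floor(min(p0[0], p1[0]) - half)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + half)) + 1, n)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - half)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + half)) + 1, n)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    v = np.array([p1[0] - p0[0], p1[1] - p0[1]])
    L2 = float(v @ v)
    wr = rr - p0[0]
    wc = cc - p0[1]
    if L2 == 0.0:
        dist = np.hypot(wr, wc)
    else:
        t = np.clip((wr * v[0] + wc * v[1]) / L2, 0.0, 1.0)
        dist = np.hypot(wr - t * v[0], wc - t * v[1])
    stroke = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0) * intensity
    region = canvas[r0:r1, c0:c1]
    np.maximum(region, stroke, out=region)


def generate_vessel_tree(params: VesselTreeParams, seed: int) -> np.ndarray:
    """Render a stochastic branching bright tree on a noisy dark background.

    Growth starts from ``n_roots`` seeded positions and proceeds segment by
    segment; at each step the direction is jittered and, with probability
    ``branch_prob``, the tip bifurcates into two daughters whose widths
    decay geometrically.  Returns a float image with intensities in [0, 1].
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.size_px
    canvas = np.zeros((n, n), dtype=float)

    # LIFO stack of growth tips: (row, col, angle, width, depth)
    stack = []
    for _ in range(params.n_roots):
        pos = rng.uniform(0.1 * n, 0.9 * n, size=2)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        stack.append((pos[0], pos[1], angle, params.initial_width_px, 0))

    jitter = np.deg2rad(params.angle_jitter_deg)
    drawn = 0
    margin = 0.05 * n
    while stack and drawn < params.max_segments:
        r, c, angle, width, depth = stack.pop()
        if depth >= params.max_depth or width < 0.6:
            continue
        if not (-margin <= r <= n + margin and -margin <= c <= n + margin):
            continue
        length = rng.uniform(params.min_segment_px, params.max_segment_px)
        r2 = r + length * np.sin(angle)
        c2 = c + length * np.cos(angle)
        _render_segment(canvas, (r, c), (r2, c2), width,
                        params.vessel_intensity)
        drawn += 1
        if rng.random() < params.branch_prob:
            split = rng.uniform(0.35, 0.8)  # radians, ~20-45 degrees
            w = width * params.width_decay
            stack.append((r2, c2, angle + split + rng.normal(0, jitter / 2),
                          w, depth + 1))
            stack.append((r2, c2, angle - split + rng.normal(0, jitter / 2),
                          w, depth + 1))
        else:
            stack.append((r2, c2, angle + rng.normal(0, jitter),
                          width * params.width_decay ** 0.25, depth + 1))

    frac = float((canvas > 0).mean())
    if frac <= 0.0 or frac >= 1.0:
        raise GenerationError(
            f"degenerate vessel rendering: foreground fraction {frac}")

    if params.background_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, params.background_noise_sd,
                                     size=canvas.shape)
    return np.clip(canvas, 0.0, 1.0)


def perturb_scan(image: np.ndarray, p: ScanPerturbation,
                 seed: int) -> np.ndarray:
    """Apply a repeat-scan perturbation to an image.

    Order of operations: bilinear sub-pixel shift, gamma contrast change,
    additive Gaussian noise.  When ``noise_reseed`` is False the noise
    field is drawn from a fixed internal seed so two scans share it; when
    True the caller-provided seed drives a fresh draw.
    """
    p.validate()
    img = np.asarray(image, dtype=float)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ConfigurationError("image intensities must lie in [0, 1]")
    if p.is_identity:
        return img.copy()
    out = img
    dx, dy = p.shift_px
    if (dx, dy) != (0.0, 0.0):
        out = ndimage.shift(out, shift=(dy, dx), order=1, mode="nearest")
        out = np.clip(out, 0.0, 1.0)
    if p.gamma != 1.0:
        out = out ** p.gamma
    if p.extra_noise_sd > 0.0:
        noise_seed = seed if p.noise_reseed else 0
        nrng = np.random.default_rng(noise_seed)
        out = out + nrng.normal(0.0, p.extra_noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# variance-components tables


def simulate_measurement_table(params: VarianceComponentsParams) -> pd.DataFrame:
    """Two-way crossed table: y_ij = mu + b_i + o_j + e_ij.

    Subject effects b_i ~ N(0, sigma_subject^2), rater effects
    o_j ~ N(0, sigma_observer^2), residuals e_ij ~ N(0, sigma_error^2).
    Returns a long-format frame with columns participant_id, rater_id,
    value.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    b = rng.normal(0.0, params.sigma_subject, size=params.n_subjects)
    o = rng.normal(0.0, params.sigma_observer, size=params.n_raters)
    e = rng.normal(0.0, params.sigma_error,
                   size=(params.n_subjects, params.n_raters))
    y = params.mu + b[:, None] + o[None, :] + e
    subjects = np.repeat(np.arange(params.n_subjects), params.n_raters)
    raters = np.tile(np.arange(params.n_raters), params.n_subjects)
    return pd.DataFrame({
        "participant_id": [f"S{i:04d}" for i in subjects],
        "rater_id": [f"R{j}" for j in raters],
        "value": y.ravel(),
    })


# ---------------------------------------------------------------------------
# cohort generation


_PLEXUSES = ("SCP", "DCP")


def _randomized_perturbation(p: ScanPerturbation,
                             rng: np.random.Generator) -> ScanPerturbation:
    """Draw a concrete perturbation within the magnitude envelope of ``p``."""
    dx, dy = p.shift_px
    gamma = p.gamma ** rng.uniform(-1.0, 1.0) if p.gamma != 1.0 else 1.0
    return ScanPerturbation(
        shift_px=(rng.uniform(-abs(dx), abs(dx)),
                  rng.uniform(-abs(dy), abs(dy))),
        noise_reseed=p.noise_reseed,
        gamma=gamma,
        extra_noise_sd=p.extra_noise_sd,
    )


def generate_cohort(n_participants: int,
                    vessel: Optional[VesselTreeParams] = None,
                    intra: Optional[ScanPerturbation] = None,
                    inter: Optional[ScanPerturbation] = None,
                    seed: int = 0):
    """Emit a full synthetic study: images plus a metadata table.

    Per participant and plexus an independent base tree is grown; scan 1
    (observer 1) receives the *inter* perturbation while scans 2 and 3
    (observer 2) receive independent draws of the *intra* perturbation.
    Each scan gets its own background-noise realisation.  Returns
    ``(images, metadata)`` where ``images`` maps
    (participant_id, plexus, scan_index) to a float image and ``metadata``
    is a DataFrame with the cohort schema.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    vessel = vessel if vessel is not None else VesselTreeParams()
    intra = intra if intra is not None else default_intra_perturbation()
    inter = inter if inter is not None else default_inter_perturbation()
    vessel.validate()
    intra.validate()
    inter.validate()
    if inter.magnitude() < intra.magnitude():
        raise ConfigurationError(
            "inter-observer perturbation must be at least as large as the "
            "intra-observer perturbation")

    root = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    base_noise_sd = vessel.background_noise_sd
    quiet = replace(vessel, background_noise_sd=0.0)

    images = {}
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        birth_year = int(meta_rng.integers(1966, 2000))
        eye = "right" if birth_year % 2 == 0 else "left"
        signal = int(meta_rng.integers(8, 11))
        for plexus in _PLEXUSES:
            ss = np.random.SeedSequence((seed, i, _PLEXUSES.index(plexus)))
            tree_seed, *scan_seeds = [int(s.generate_state(1)[0])
                                      for s in ss.spawn(4)]
            base = generate_vessel_tree(quiet, tree_seed)
            for scan_index, scan_seed in zip((1, 2, 3), scan_seeds):
                srng = np.random.default_rng(scan_seed)
                envelope = inter if scan_index == 1 else intra
                pert = _randomized_perturbation(envelope, srng)
                img = perturb_scan(base, pert, scan_seed)
                if base_noise_sd > 0:
                    img = np.clip(
                        img + srng.normal(0.0, base_noise_sd, img.shape),
                        0.0, 1.0)
                observer = 1 if scan_index == 1 else 2
                images[(pid, plexus, scan_index)] = img
                rows.append({
                    "participant_id": pid,
                    "birth_year": birth_year,
                    "observer_id": observer,
                    "scan_index": scan_index,
                    "plexus": plexus,
                    "eye": eye,
                    "signal_strength": signal,
                    "artefact_flag": False,
                    "image_path": f"{pid}_{plexus}_scan{scan_index}.png",
                })
    return images, pd.DataFrame(rows)


def default_intra_perturbation() -> ScanPerturbation:
    """Small same-observer scan-to-scan change."""
    return ScanPerturbation(shift_px=(0.3, 0.3), noise_reseed=True,
                            gamma=1.0, extra_noise_sd=0.005)


def default_inter_perturbation() -> ScanPerturbation:
    """Larger between-observer change (re-centration, head position)."""
    return ScanPerturbation(shift_px=(3.0, 3.0), noise_reseed=True,
                            gamma=1.08, extra_noise_sd=0.02)
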