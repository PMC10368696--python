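"""Image statistics for mRNP-granule (P-body) formation and cortical signal.

Two readouts are implemented, both on 2-D grayscale images (maximum
projections of confocal stacks):

* **granularity** — the fraction of the oocyte area covered by segmented
  P-bodies (area of granule mask / area of oocyte mask), the scalar measure
  of P-body formation; groups of egg chambers are compared with the Welch
  two-sample t test;
* **boundary profile** — mean fluorescence intensity as a function of signed
  perpendicular offset from a cell–cell boundary, averaged along the
  boundary-parallel axis of a rectangular ROI and normalized to the maximum
  of the averaged profile.

P-bodies are segmented by thresholding within the oocyte mask (Otsu by
default, or mean + k*sd) followed by removal of small 8-connected
components. A synthetic egg-chamber generator provides ground-truthed
fixtures: punctate granules over background for the granularity channel and
a cortically enriched band for the boundary channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.transform import rotate as _sk_rotate

from .datamodel import ConfigError, ValidationError
from .stats import GroupTestResult, welch_t


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValidationError(f"image must be 2-D and >= 16x16, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise ValidationError("image contains non-finite values")
    if image.min() < 0:
        raise ValidationError("image intensities must be non-negative")
    return image


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a z-stack (z, y, x) to 2-D."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack
    return stack.max(axis=0)


def segment_pbodies(
    image: np.ndarray,
    oocyte_mask: np.ndarray,
    *,
    method: str = "otsu",
    k: float = 2.0,
    min_size: int = 9,
) -> np.ndarray:
    """Segment P-bodies inside the oocyte mask.

    The threshold is computed from pixels within the mask only (Otsu by
    default; ``method='mean_sd'`` uses mean + k*sd). 8-connected components
    smaller than ``min_size`` pixels are removed. The result is a boolean
    mask, a subset of the oocyte mask. A constant image yields an empty
    mask with a warning.
    """
    image = _check_image(image)
    oocyte_mask = np.asarray(oocyte_mask, dtype=bool)
    if oocyte_mask.shape != image.shape:
        raise ValidationError("oocyte mask shape differs from image shape")
    if not oocyte_mask.any():
        raise ValidationError("oocyte mask is empty")
    inside = image[oocyte_mask]
    if np.ptp(inside) == 0:
        warnings.warn("constant intensity within oocyte mask; no P-bodies segmented")
        return np.zeros_like(oocyte_mask)
    if method == "otsu":
        thr = threshold_otsu(inside)
    elif method == "mean_sd":
        thr = float(inside.mean() + k * inside.std())
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    binary = (image > thr) & oocyte_mask
    if min_size > 1:
        # remove components strictly smaller than min_size pixels
        binary = remove_small_objects(binary, max_size=min_size - 1, connectivity=2)
    return binary


def granularity(pbody_mask: np.ndarray, oocyte_mask: np.ndarray) -> float:
    """Area covered by P-bodies divided by total oocyte area (pixel counts)."""
    pbody_mask = np.asarray(pbody_mask, dtype=bool)
    oocyte_mask = np.asarray(oocyte_mask, dtype=bool)
    if pbody_mask.shape != oocyte_mask.shape:
        raise ValidationError("mask shapes differ")
    if not oocyte_mask.any():
        raise ValidationError("oocyte mask is empty")
    if (pbody_mask & ~oocyte_mask).any():
        raise ValidationError("P-body mask extends outside the oocyte mask")
    return float(pbody_mask.sum()) / float(oocyte_mask.sum())


def compare_granularity(group_a, group_b, label: str = "granularity") -> GroupTestResult:
    """Welch two-sample t test between two groups of per-image granularities."""
    return welch_t(group_a, group_b, label=label)


@dataclass
class BoundaryProfile:
    """Normalized mean-intensity profile across a cell boundary.

    ``offsets`` are signed pixel distances from the ROI centre line (0 at the
    boundary when the ROI is centred on it); ``values`` are means along the
    boundary-parallel axis, normalized so the maximum is 1 when any signal is
    present (``flagged_zero`` marks all-zero profiles).
    """

    offsets: np.ndarray
    values: np.ndarray
    n_pixels: int
    flagged_zero: bool = False


def boundary_profile(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    *,
    boundary_axis: str = "vertical",
    angle_deg: float = 0.0,
) -> BoundaryProfile:
    """Fluorescence profile perpendicular to a cell boundary.

    ``roi`` is a half-open rectangle (row0, row1, col0, col1) in 0-based
    pixel coordinates; its extent perpendicular to the boundary must be odd
    so offsets are symmetric about 0. ``boundary_axis`` gives the direction
    the boundary runs ('vertical' boundaries produce horizontal offsets).
    A non-zero ``angle_deg`` pre-rotates the image (bilinear) so the
    boundary becomes axis-aligned.
    """
    image = _check_image(image)
    if angle_deg != 0.0:
        image = _sk_rotate(image, angle_deg, order=1, preserve_range=True)
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValidationError(f"ROI {roi} out of bounds for image {image.shape}")
    patch = image[r0:r1, c0:c1]
    if boundary_axis == "vertical":
        profile = patch.mean(axis=0)  # one value per column offset
        n_avg = patch.shape[0]
    elif boundary_axis == "horizontal":
        profile = patch.mean(axis=1)
        n_avg = patch.shape[1]
    else:
        raise ValueError(f"boundary_axis must be 'vertical' or 'horizontal', got {boundary_axis!r}")
    width = len(profile)
    if width % 2 != 1:
        raise ValidationError(
            "ROI extent perpendicular to the boundary must be odd for symmetric offsets"
        )
    offsets = np.arange(width) - width // 2
    peak = profile.max()
    if peak <= 0:
        return BoundaryProfile(offsets, np.zeros(width), n_avg, flagged_zero=True)
    return BoundaryProfile(offsets, profile / peak, n_avg, flagged_zero=False)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass
class EggChamberParams:
    """Parameters of the synthetic egg-chamber image fixture.

    The oocyte is a centred disk; P-bodies are non-overlapping disks of
    ``pbody_radius`` placed inside it until ``target_granularity`` of the
    oocyte area is covered (or ``n_pbodies`` disks when given explicitly).
    The boundary channel has a vertical band of width ``boundary_width`` at
    ``boundary_col`` whose intensity is ``boundary_enrichment`` times the
    cytoplasmic background. Gaussian noise sd ``noise_sd`` applies to both
    channels (intensities clipped at 0).
    """

    shape: tuple[int, int] = (256, 256)
    oocyte_radius: int = 100
    pbody_radius: int = 5
    target_granularity: float = 0.05
    n_pbodies: int | None = None
    background: float = 100.0
    pbody_intensity: float = 1000.0
    boundary_col: int = 128
    boundary_width: int = 3
    boundary_enrichment: float = 3.0
    noise_sd: float = 10.0
    pixel_size_um: float = 0.2

    def validate(self) -> None:
        if min(self.shape) < 16:
            raise ConfigError("image must be at least 16x16")
        if not 0 <= self.target_granularity <= 1:
            raise ConfigError("target_granularity must lie in [0, 1]")
        if self.pbody_radius < 1 or self.oocyte_radius < 4 * self.pbody_radius:
            raise ConfigError("oocyte must be much larger than one P-body")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.boundary_col < self.shape[1]:
            raise ConfigError("boundary_col outside image")


@dataclass
class SyntheticEggChamber:
    """One synthetic egg chamber: per-channel images, masks, and ground truth."""

    channels: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    truth: dict[str, float] = field(default_factory=dict)


def _disk_mask(shape: tuple[int, int], centre: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def make_synthetic_eggchamber(
    params: EggChamberParams, seed: int = 0
) -> SyntheticEggChamber:
    """Deterministic synthetic egg chamber with true P-body mask and boundary."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    shape = params.shape
    centre = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    oocyte = _disk_mask(shape, centre, params.oocyte_radius)
    oocyte_area = int(oocyte.sum())

    disk_area = int(_disk_mask((64, 64), (32, 32), params.pbody_radius).sum())
    if params.n_pbodies is not None:
        n_pbodies = params.n_pbodies
    else:
        n_pbodies = int(round(params.target_granularity * oocyte_area / disk_area))
    if n_pbodies * disk_area > 0.6 * oocyte_area:
        raise ConfigError("requested P-bodies exceed the oocyte capacity")

    pbody = np.zeros(shape, dtype=bool)
    placed = 0
    attempts = 0
    margin = params.pbody_radius + 2
    occupied = np.zeros(shape, dtype=bool)
    while placed < n_pbodies:
        attempts += 1
        if attempts > 200 * max(n_pbodies, 1):
            raise ConfigError("could not place requested P-bodies without overlap")
        r = centre[0] + rng.uniform(-1, 1) * (params.oocyte_radius - margin)
        c = centre[1] + rng.uniform(-1, 1) * (params.oocyte_radius - margin)
        if (r - centre[0]) ** 2 + (c - centre[1]) ** 2 > (params.oocyte_radius - margin) ** 2:
            continue
        candidate = _disk_mask(shape, (r, c), params.pbody_radius)
        # keep granules separated so segmentation sees distinct components
        halo = _disk_mask(shape, (r, c), params.pbody_radius + 2)
        if (halo & occupied).any():
            continue
        pbody |= candidate
        occupied |= halo
        placed += 1

    granule_img = np.full(shape, params.background, dtype=float)
    granule_img[~oocyte] = 0.25 * params.background
    granule_img[pbody] = params.pbody_intensity
    granule_img += rng.normal(0.0, params.noise_sd, size=shape)
    granule_img = np.maximum(granule_img, 0.0)

    boundary_img = np.full(shape, params.background, dtype=float)
    half_w = params.boundary_width // 2
    c0 = max(params.boundary_col - half_w, 0)
    c1 = min(params.boundary_col + half_w + 1, shape[1])
    boundary_img[:, c0:c1] = params.background * params.boundary_enrichment
    boundary_img += rng.normal(0.0, params.noise_sd, size=shape)
    boundary_img = np.maximum(boundary_img, 0.0)

    true_granularity = float(pbody.sum()) / float(oocyte_area)
    return SyntheticEggChamber(
        channels={"pbody": granule_img, "boundary": boundary_img},
        masks={"oocyte": oocyte, "pbody_true": pbody},
        truth={
            "granularity": true_granularity,
            "boundary_col": float(params.boundary_col),
            "boundary_enrichment": float(params.boundary_enrichment),
            "n_pbodies": float(placed),
        },
    )
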