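"""Quantification of hind-wing mimicry spots from images.

The measurement protocol mirrors standard practice for this trait:

1. rotate the image about landmark 1 (intersection of the second anterior
   cubitus vein and the cell border) so that the landmark-1 → landmark-2
   (tip of the tail vein) axis points straight down;
2. demarcate the analysis region as the wing area at or below the
   horizontal line through landmark 1;
3. segment white and red spot pixels, either with fixed colour cuts
   (specimens whose white spot is distinct) or, for specimens whose white
   and red spots are partially fused, with a per-specimen brightness
   threshold: the mean minus one standard deviation of the brightness of
   points sampled from the clearly white area;
4. report each spot area divided by the analysis-region area.

Coordinates are 0-based with origin at the top-left; ``x`` is the column
index and ``y`` the row index, so "below" a horizontal line means a larger
``y``.  The analysis region includes landmark 1's own row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import transform as sktransform

__all__ = [
    "WingImage",
    "LandmarkPair",
    "ThresholdSpec",
    "SpotMeasurement",
    "SegmentationConfig",
    "DegenerateGeometryError",
    "grey_convert",
    "align_wing",
    "wing_mask",
    "analysis_region",
    "segment_distinct",
    "segment_fused",
    "measure",
]


class DegenerateGeometryError(ValueError):
    """Raised for coincident landmarks or empty analysis regions."""


@dataclass
class WingImage:
    """An RGB wing photograph (``pixels`` is an (H, W, 3) uint8 array)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) raster, got shape {px.shape}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LandmarkPair:
    """Landmarks 1 and 2 as (x, y) coordinates; sub-pixel precision allowed."""

    landmark1: tuple[float, float]
    landmark2: tuple[float, float]

    def __post_init__(self) -> None:
        self.landmark1 = (float(self.landmark1[0]), float(self.landmark1[1]))
        self.landmark2 = (float(self.landmark2[0]), float(self.landmark2[1]))
        if self.landmark1 == self.landmark2:
            raise DegenerateGeometryError("landmarks 1 and 2 coincide")


@dataclass
class ThresholdSpec:
    """How to derive the fused-spot brightness threshold.

    Either ``sampled_points`` gives explicit (x, y) sample locations in the
    clearly white area, or ``n_sample_points`` points are drawn uniformly
    at random (governed by ``seed``) from a white candidate region.
    """

    n_sample_points: int = 30
    sampled_points: Optional[Sequence[tuple[float, float]]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.sampled_points) if self.sampled_points is not None else self.n_sample_points
        if n < 2:
            raise ValueError("at least 2 sample points are required (SD undefined below 2)")


@dataclass
class SegmentationConfig:
    """Colour cuts for the distinct-spot rule.

    ``white_cut``: minimum grey level for a white pixel.  ``achromatic_cut``:
    maximum R/G/B channel spread for a white pixel.  ``red_margin``: by how
    much R must exceed both G and B for a red pixel.
    """

    white_cut: float = 128.0
    achromatic_cut: float = 40.0
    red_margin: float = 50.0
    background_tol: float = 60.0


@dataclass
class SpotMeasurement:
    """White/red spot areas and relative sizes for one specimen.

    ``wing_area_px`` is the analysis-region pixel count (the wing area below
    the landmark-1 line), so ``white_rel = white_area_px / wing_area_px``.
    """

    white_area_px: int
    red_area_px: int
    wing_area_px: int
    white_rel: float
    red_rel: float
    method: str  # "distinct" or "fused"
    threshold_used: Optional[float] = None


_LUMA = np.array([0.299, 0.587, 0.114])


def grey_convert(image: WingImage | np.ndarray) -> np.ndarray:
    """Standard luma grey conversion, 0.299 R + 0.587 G + 0.114 B in [0, 255]."""
    px = image.pixels if isinstance(image, WingImage) else np.asarray(image)
    grey = px[..., :3].astype(float) @ _LUMA
    return np.clip(grey, 0.0, 255.0)


def _background_colour(px: np.ndarray) -> np.ndarray:
    """Median colour of the image border, taken as the background."""
    border = np.concatenate(
        [px[0, :, :], px[-1, :, :], px[:, 0, :], px[:, -1, :]], axis=0
    )
    return np.median(border.astype(float), axis=0)


def _rotation_about(angle_rad: float, pivot: tuple[float, float]) -> np.ndarray:
    """Homogeneous 3x3 matrix rotating (x, y) points by ``angle_rad`` about ``pivot``."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    px, py = pivot
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    to_origin = np.array([[1, 0, -px], [0, 1, -py], [0, 0, 1]], dtype=float)
    back = np.array([[1, 0, px], [0, 1, py], [0, 0, 1]], dtype=float)
    return back @ rot @ to_origin


def align_wing(
    image: WingImage, lm: LandmarkPair
) -> tuple[WingImage, LandmarkPair]:
    """Rotate the image about landmark 1 so landmark 1 → landmark 2 points down (+y).

    The output canvas is padded (with the border/background colour) so that
    no pixel of the input is lost; the returned landmarks are the transformed
    coordinates on the new canvas.
    """
    px = image.pixels
    h, w = px.shape[:2]
    x1, y1 = lm.landmark1
    x2, y2 = lm.landmark2
    if not (0 <= x1 < w and 0 <= y1 < h and 0 <= x2 < w and 0 <= y2 < h):
        raise ValueError("landmarks must lie inside the image")
    vx, vy = x2 - x1, y2 - y1
    # rotate the vector (vx, vy) onto (0, +|v|)
    theta = np.pi / 2 - np.arctan2(vy, vx)
    matrix = _rotation_about(theta, (x1, y1))

    corners = np.array([[0, 0, 1], [w - 1, 0, 1], [0, h - 1, 1], [w - 1, h - 1, 1]], float)
    rotated = (matrix @ corners.T).T[:, :2]
    mins = rotated.min(axis=0)
    maxs = rotated.max(axis=0)
    shift = np.where(mins < 0, -mins, 0.0)
    out_w = int(np.ceil(maxs[0] + shift[0])) + 1
    out_h = int(np.ceil(maxs[1] + shift[1])) + 1
    matrix = np.array([[1, 0, shift[0]], [0, 1, shift[1]], [0, 0, 1]], float) @ matrix

    inv = np.linalg.inv(matrix)
    bg = _background_colour(px)
    out = np.empty((out_h, out_w, 3), dtype=float)
    for ch in range(3):
        out[..., ch] = sktransform.warp(
            px[..., ch].astype(float),
            inverse_map=sktransform.AffineTransform(matrix=inv),
            output_shape=(out_h, out_w),
            order=1,
            mode="constant",
            cval=bg[ch],
            preserve_range=True,
        )
    out_px = np.clip(np.round(out), 0, 255).astype(np.uint8)

    p1 = matrix @ np.array([x1, y1, 1.0])
    p2 = matrix @ np.array([x2, y2, 1.0])
    new_lm = LandmarkPair((p1[0], p1[1]), (p2[0], p2[1]))
    return WingImage(out_px), new_lm


def wing_mask(
    image: WingImage,
    lm: LandmarkPair,
    background_tol: float = 60.0,
) -> np.ndarray:
    """Wing raster: the connected non-background component containing the
    landmark midpoint.

    The background colour is estimated as the median border colour; a pixel
    is background when every channel is within ``background_tol`` of it.
    """
    px = image.pixels.astype(float)
    bg = _background_colour(px)
    dist = np.abs(px - bg).max(axis=2)
    non_bg = dist > background_tol
    if not non_bg.any():
        raise ValueError("no non-background pixels found (uniform image?)")
    labels = skmeasure.label(non_bg, connectivity=2)
    mx = (lm.landmark1[0] + lm.landmark2[0]) / 2.0
    my = (lm.landmark1[1] + lm.landmark2[1]) / 2.0
    r, c = int(round(my)), int(round(mx))
    h, w = labels.shape
    lab = 0
    # search a small neighbourhood in case the midpoint rounds onto a noise hole
    for radius in range(0, 6):
        rs = slice(max(r - radius, 0), min(r + radius + 1, h))
        cs = slice(max(c - radius, 0), min(c + radius + 1, w))
        window = labels[rs, cs]
        nz = window[window > 0]
        if nz.size:
            lab = np.bincount(nz).argmax()
            break
    if lab == 0:
        raise ValueError("landmark midpoint does not fall on a non-background component")
    return labels == lab


def analysis_region(
    image: WingImage | np.ndarray,
    lm: LandmarkPair,
    wing: np.ndarray,
) -> np.ndarray:
    """Wing pixels at or below the horizontal line through landmark 1.

    The image must already be aligned (landmark axis vertical).
    """
    row = int(round(lm.landmark1[1]))
    region = wing.copy()
    region[: max(row, 0), :] = False
    if not region.any():
        raise DegenerateGeometryError("analysis region is empty")
    return region


def segment_distinct(
    image: WingImage,
    region: np.ndarray,
    config: SegmentationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Colour-cut segmentation for specimens with a distinct white spot.

    White: grey value above ``white_cut`` and channel spread below
    ``achromatic_cut``.  Red: R exceeds both G and B by ``red_margin`` and
    the pixel is not already white.  Both are restricted to ``region``.
    Empty masks are valid.
    """
    cfg = config or SegmentationConfig()
    px = image.pixels.astype(float)
    grey = grey_convert(image)
    spread = px.max(axis=2) - px.min(axis=2)
    white = (grey > cfg.white_cut) & (spread < cfg.achromatic_cut) & region
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    red = (r > g + cfg.red_margin) & (r > b + cfg.red_margin) & region & ~white
    return white, red


def segment_fused(
    image: WingImage,
    region: np.ndarray,
    tspec: ThresholdSpec,
    sample_region: Optional[np.ndarray] = None,
    config: SegmentationConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Brightness-threshold segmentation for fused white/red spots.

    The threshold is the mean minus one sample standard deviation (n−1
    denominator) of the brightness of the sampled points; a pixel belongs to
    the white spot when its brightness is strictly greater than the
    threshold.  When ``tspec.sampled_points`` is absent, points are drawn
    uniformly without replacement from ``sample_region`` (default: the
    distinct-rule white mask, i.e. the clearly white area).
    """
    grey = grey_convert(image)
    if tspec.sampled_points is not None:
        pts = [(int(round(y)), int(round(x))) for x, y in tspec.sampled_points]
        for rr, cc in pts:
            if not (0 <= rr < region.shape[0] and 0 <= cc < region.shape[1]) or not region[rr, cc]:
                raise ValueError(f"sampled point (x={cc}, y={rr}) lies outside the analysis region")
        values = np.array([grey[rr, cc] for rr, cc in pts], float)
    else:
        if sample_region is None:
            sample_region, _ = segment_distinct(image, region, config)
        # sample the *clearly* white area: erode away the boundary pixels,
        # whose brightness is diluted by resampling, unless that empties it
        eroded = ndimage.binary_erosion(sample_region & region, iterations=2)
        if eroded.sum() >= tspec.n_sample_points:
            sample_region = eroded
        candidates = np.flatnonzero(sample_region & region)
        if candidates.size < tspec.n_sample_points:
            raise ValueError(
                f"clearly-white area has only {candidates.size} pixels; "
                f"{tspec.n_sample_points} sample points requested"
            )
        rng = np.random.default_rng(tspec.seed)
        chosen = rng.choice(candidates, size=tspec.n_sample_points, replace=False)
        values = grey.ravel()[chosen]
    if values.size < 2:
        raise ValueError("at least 2 sampled brightness values are required")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "all sampled brightnesses identical: SD = 0, so pixels exactly at the "
            "sampled brightness are excluded by the strict threshold",
            stacklevel=2,
        )
    threshold = float(np.mean(values)) - sd
    white = region & (grey > threshold)
    return white, threshold


def measure(
    image: WingImage,
    lm: LandmarkPair,
    tspec: Optional[ThresholdSpec] = None,
    config: SegmentationConfig | None = None,
    wing: Optional[np.ndarray] = None,
) -> SpotMeasurement:
    """Full measurement: align, demarcate, segment, and report relative areas.

    With ``tspec`` given the white spot uses the fused-spot brightness rule,
    otherwise the distinct colour cuts; the red area always comes from the
    distinct rule.  ``wing`` optionally supplies an externally drawn wing
    mask (in the input image frame), bypassing automatic background analysis.
    """
    cfg = config or SegmentationConfig()
    aligned, alm = align_wing(image, lm)
    if wing is not None:
        if wing.shape != image.pixels.shape[:2]:
            raise ValueError("supplied wing mask does not match the image shape")
        # carry the external mask through the same alignment
        mask_img = WingImage(np.repeat(wing[:, :, None].astype(np.uint8) * 255, 3, axis=2))
        warped, _ = align_wing(mask_img, lm)
        wmask = warped.pixels[..., 0] > 127
    else:
        wmask = wing_mask(aligned, alm, background_tol=cfg.background_tol)
    region = analysis_region(aligned, alm, wmask)

    white_d, red = segment_distinct(aligned, region, cfg)
    if tspec is not None:
        white, threshold = segment_fused(aligned, region, tspec, sample_region=white_d, config=cfg)
        method = "fused"
    else:
        white, threshold = white_d, None
        method = "distinct"

    wing_area = int(region.sum())
    white_area = int(white.sum())
    red_area = int((red & ~white).sum())
    return SpotMeasurement(
        white_area_px=white_area,
        red_area_px=red_area,
        wing_area_px=wing_area,
        white_rel=white_area / wing_area,
        red_rel=red_area / wing_area,
        method=method,
        threshold_used=threshold,
    )
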