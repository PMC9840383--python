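"""Fluorescence image quantification: thresholds, colocalization, ROIs.

Covers the image-analysis layer of the study design: automatic (Otsu)
thresholding of each channel, thresholded Mander's colocalization
coefficients between a green axon-terminal channel and a red
presynaptic-marker channel, and counts of supra-threshold fiber pixels
inside randomly placed rectangular ROIs (0.3 × 0.4 mm by default) for
anterior-vs-posterior group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from fiberphot.stats import TTestResult, unpaired_t

__all__ = [
    "ROISpec",
    "ColocResult",
    "auto_threshold",
    "manders_coefficients",
    "roi_fiber_pixel_count",
    "place_random_rois",
    "compare_regions",
]

#: default scale when image metadata is absent: 1 px = 1 µm
DEFAULT_PIXEL_SIZE_MM = 0.001


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest in physical units.

    Origin is the (row, col) corner in mm; extent is (height, width)
    in mm — default 0.3 × 0.4 mm.
    """

    origin_mm: tuple
    extent_mm: tuple = (0.3, 0.4)
    label: str = ""

    def to_slices(self, pixel_size_mm: float, shape: tuple) -> tuple:
        r0 = int(round(self.origin_mm[0] / pixel_size_mm))
        c0 = int(round(self.origin_mm[1] / pixel_size_mm))
        r1 = r0 + int(round(self.extent_mm[0] / pixel_size_mm))
        c1 = c0 + int(round(self.extent_mm[1] / pixel_size_mm))
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValueError(
                f"ROI {self.label or self.origin_mm} extends outside the "
                f"{shape[0]}x{shape[1]} px image"
            )
        return slice(r0, r1), slice(c0, c1)


@dataclass(frozen=True)
class ColocResult:
    """Mander's coefficients and the thresholds that produced them."""

    m1: float
    m2: float
    threshold_green: float
    threshold_red: float

    def __post_init__(self) -> None:
        for v in (self.m1, self.m2):
            if not 0.0 <= v <= 1.0:
                raise ValueError("Mander's coefficients must lie in [0, 1]")


def auto_threshold(img: np.ndarray) -> float:
    """Automatic intensity threshold by Otsu's method.

    Maximizes between-class variance over a 256-bin histogram spanning
    the observed intensity range.

    Raises
    ------
    ValueError
        For a constant image (no threshold separates anything).
    """
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("constant image: automatic threshold undefined")
    return float(threshold_otsu(img, nbins=256))


def manders_coefficients(
    green: np.ndarray,
    red: np.ndarray,
    threshold_green: float | None = None,
    threshold_red: float | None = None,
    thresholded: bool = True,
) -> ColocResult:
    """Mander's M1/M2 overlap coefficients between two channels.

    M1 is the fraction of green intensity (over green-positive pixels)
    that falls on red-positive pixels; M2 is the symmetric fraction for
    red.  Thresholds default to each channel's Otsu value.  With
    ``thresholded=False`` the classic coefficients are computed
    instead: all green intensity in the denominator, red > 0 defining
    overlap (and vice versa).
    """
    g = np.asarray(green, dtype=float)
    r = np.asarray(red, dtype=float)
    if g.shape != r.shape:
        raise ValueError(f"channel shapes differ: {g.shape} vs {r.shape}")
    thr_g = auto_threshold(g) if threshold_green is None else threshold_green
    thr_r = auto_threshold(r) if threshold_red is None else threshold_red
    if thresholded:
        g_pos = g > thr_g
        r_pos = r > thr_r
        g_total = g[g_pos].sum()
        r_total = r[r_pos].sum()
        if g_total <= 0 or r_total <= 0:
            raise ValueError("a channel has zero supra-threshold intensity")
        m1 = g[g_pos & r_pos].sum() / g_total
        m2 = r[g_pos & r_pos].sum() / r_total
    else:
        g_total = g.sum()
        r_total = r.sum()
        if g_total <= 0 or r_total <= 0:
            raise ValueError("a channel has zero total intensity")
        m1 = g[r > 0].sum() / g_total
        m2 = r[g > 0].sum() / r_total
    return ColocResult(float(m1), float(m2), float(thr_g), float(thr_r))


def roi_fiber_pixel_count(
    img: np.ndarray,
    threshold: float,
    rois: list[ROISpec],
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM,
) -> list[int]:
    """Count supra-threshold pixels inside each ROI.

    The per-ROI counts are the unit of the anterior/posterior fiber
    density comparison.
    """
    img = np.asarray(img, dtype=float)
    counts = []
    for roi in rois:
        rs, cs = roi.to_slices(pixel_size_mm, img.shape)
        counts.append(int(np.sum(img[rs, cs] > threshold)))
    return counts


def place_random_rois(
    image_shape: tuple,
    region_mask: np.ndarray,
    n_rois: int,
    seed: int,
    extent_mm: tuple = (0.3, 0.4),
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM,
    label: str = "",
    max_tries: int = 10000,
) -> list[ROISpec]:
    """Randomly allocate ROIs fully inside a region mask.

    Rejection-samples corner positions until each candidate rectangle
    lies entirely within ``region_mask`` (e.g. the anterior or
    posterior part of the section).
    """
    if region_mask.shape != tuple(image_shape):
        raise ValueError("region mask must match the image shape")
    h_px = int(round(extent_mm[0] / pixel_size_mm))
    w_px = int(round(extent_mm[1] / pixel_size_mm))
    if h_px > image_shape[0] or w_px > image_shape[1]:
        raise ValueError("ROI larger than the image at this pixel size")
    rng = np.random.default_rng(seed)
    rois: list[ROISpec] = []
    tries = 0
    while len(rois) < n_rois:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_rois} ROIs inside region {label!r}"
            )
        tries += 1
        r0 = int(rng.integers(0, image_shape[0] - h_px + 1))
        c0 = int(rng.integers(0, image_shape[1] - w_px + 1))
        if region_mask[r0:r0 + h_px, c0:c0 + w_px].all():
            rois.append(ROISpec(
                origin_mm=(r0 * pixel_size_mm, c0 * pixel_size_mm),
                extent_mm=extent_mm,
                label=f"{label}{len(rois)}",
            ))
    return rois


def compare_regions(
    anterior_counts: np.ndarray,
    posterior_counts: np.ndarray,
) -> TTestResult:
    """Unpaired two-tailed t test between per-ROI pixel counts."""
    return unpaired_t(np.asarray(anterior_counts, dtype=float),
                      np.asarray(posterior_counts, dtype=float))
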