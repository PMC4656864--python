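"""Candidate detection and region extraction for spore micrographs.

A frame typically shows a few hundred sparse, roughly circular spore images
on a dark background.  Candidates are located with a circular Hough
transform on a gradient edge map; an anticollision filter suppresses
double-counts of elongated spores that register as two nearby circles; each
surviving candidate yields a background-corrected 27 x 27-pixel fitting
region.  Detection favours recall — false positives are removed downstream
by the sigma-based quality control of the fitter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

log = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "CandidateRegion",
    "REGION_SIZE",
    "detect_candidates",
    "anticollision_filter",
    "extract_region",
]

#: side of the square fitting region, pixels
REGION_SIZE = 27
_HALF = REGION_SIZE // 2


@dataclass
class Frame:
    """A single micrograph: 2D intensity array plus object-frame pixel width
    (nm) and free-form metadata (source file, frame id, ...)."""

    image: np.ndarray
    pixel_width: float = 74.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("frame image must be 2D grayscale")

    @property
    def frame_id(self):
        return self.metadata.get("frame_id", 0)


@dataclass
class CandidateRegion:
    """A segmented fitting region.

    ``crop`` is the background-corrected 27 x 27 crop: the raw crop minus
    ``zero_level`` (the median of pixels darker than the crop mean), clipped
    at zero.  ``strength`` is the Hough accumulator response used for
    collision resolution.
    """

    index: int
    center_pixel: tuple[int, int]  # (row, col)
    crop: np.ndarray
    zero_level: float
    strength: float = 0.0
    pixel_width: float = 74.0


def _background_zero_level(raw_crop: np.ndarray) -> float:
    """Median of pixels strictly darker than the crop mean; for a constant
    crop (nothing below the mean) falls back to the crop minimum."""
    below = raw_crop[raw_crop < raw_crop.mean()]
    if below.size == 0:
        return float(raw_crop.min())
    return float(np.median(below))


def extract_region(frame: Frame, center: tuple[int, int],
                   index: int = 0, strength: float = 0.0):
    """Extract the background-corrected fitting region around ``center``.

    Returns None (with a log entry) if the 27 x 27 crop would leave the
    frame; zero-padding would bias the fitted PSF radius.
    """
    row, col = int(center[0]), int(center[1])
    n_rows, n_cols = frame.image.shape
    if (row < _HALF or col < _HALF
            or row > n_rows - 1 - _HALF or col > n_cols - 1 - _HALF):
        log.info("candidate at (%d, %d) rejected: too near frame edge",
                 row, col)
        return None
    raw = frame.image[row - _HALF: row + _HALF + 1,
                      col - _HALF: col + _HALF + 1]
    zero = _background_zero_level(raw)
    crop = np.clip(raw - zero, 0.0, None)
    return CandidateRegion(index=index, center_pixel=(row, col), crop=crop,
                           zero_level=zero, strength=strength,
                           pixel_width=frame.pixel_width)


def _greedy_suppress(entries, min_distance):
    """Keep strongest entries first, dropping any within min_distance of a
    survivor.  entries: list of (strength, row, col, payload)."""
    survivors = []
    for e in sorted(entries, key=lambda t: -t[0]):
        if all((e[1] - s[1]) ** 2 + (e[2] - s[2]) ** 2 >= min_distance ** 2
               for s in survivors):
            survivors.append(e)
    return survivors


def detect_candidates(frame: Frame, min_radius_px: int = 4,
                      max_radius_px: int = 12, peak_threshold: float = 0.8,
                      smoothing_sigma: float = 1.0) -> list[CandidateRegion]:
    """Locate circular features with a circular Hough transform.

    The edge map is the Sobel gradient magnitude after light Gaussian
    smoothing, binarised at the Otsu threshold (the Hough accumulator
    counts votes from edge pixels); accumulator peaks above
    ``peak_threshold`` times the maximum become candidates.  The radius
    range 4-12 px (~300-900 nm at 74 nm/px) spans typical spore layer
    radii.  Detected circles that overlap (centre distance below the sum
    of their radii) are one circular feature and are merged, strongest
    wins; candidates whose fitting region would leave the frame are
    dropped.
    """
    img = frame.image
    if img.size == 0 or not np.isfinite(img).all() or img.max() == img.min():
        warnings.warn("frame is blank or degenerate; no candidates",
                      stacklevel=2)
        return []
    smooth = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    edges = sobel(smooth)
    binary = edges > threshold_otsu(edges)
    radii = np.arange(min_radius_px, max_radius_px + 1)
    accum = hough_circle(binary, radii)
    threshold = peak_threshold * accum.max()
    accums, cx, cy, crad = hough_circle_peaks(
        accum, radii, min_xdistance=min_radius_px,
        min_ydistance=min_radius_px, threshold=threshold,
        total_num_peaks=10000)
    # merge overlapping circles: one circular feature, strongest wins
    entries = []
    for a, x, y, r in sorted(zip(accums, cx, cy, crad), key=lambda t: -t[0]):
        if all((y - ky) ** 2 + (x - kx) ** 2 >= (r + kr) ** 2
               for _, ky, kx, kr in entries):
            entries.append((float(a), int(y), int(x), int(r)))
    regions = []
    for strength, row, col, _ in entries:
        region = extract_region(frame, (row, col), index=len(regions),
                                strength=strength)
        if region is not None:
            regions.append(region)
    log.info("frame %s: %d candidate(s) detected", frame.frame_id,
             len(regions))
    return regions


def anticollision_filter(candidates: list[CandidateRegion],
                         collision_distance: float = 13.0
                         ) -> list[CandidateRegion]:
    """Suppress double-counts: of any two candidates closer than
    ``collision_distance`` pixels (default: half the fitting-region width,
    so two circles on one elongated spore collide), the stronger Hough
    response survives.  Idempotent."""
    entries = [(c.strength, c.center_pixel[0], c.center_pixel[1], c)
               for c in candidates]
    survivors = _greedy_suppress(entries, collision_distance)
    kept = [e[3] for e in survivors]
    kept.sort(key=lambda c: c.index)
    for i, c in enumerate(kept):
        c.index = i
    return kept
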