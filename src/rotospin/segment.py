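"""Binarization and connected-domain labeling.

The enhanced image is thresholded with the Otsu criterion (maximum
between-class variance over the 256 candidate grey levels, ties resolved to
the smallest threshold for determinism), cleaned by small-object removal
and a single disk dilation to smooth the cell outline, and every
8-connected foreground component is labeled with its pixel area, tightest
bounding box and centroid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .datatypes import Detection

__all__ = [
    "otsu_threshold",
    "binarize",
    "remove_small_objects",
    "dilate",
    "label_components",
    "segment_frame",
]

DEFAULT_MIN_AREA = 30  # px; ~ a quarter of a 24 px-diameter cell footprint
DEFAULT_DILATE_RADIUS = 1


def otsu_threshold(image: np.ndarray) -> int:
    """Between-class-variance-maximizing grey threshold t* in [0, 254].

    Pixels with value > t* are foreground.  Computed from the 256-bin
    histogram with cumulative sums; among ties the smallest t* is returned.
    """
    img = np.asarray(image)
    if img.min() == img.max():
        raise ValueError("constant image cannot be thresholded")
    hist = np.bincount(np.clip(np.rint(img).astype(int), 0, 255).ravel(), minlength=256).astype(float)
    n = hist.sum()
    w0 = np.cumsum(hist)  # background pixel count for t = 0..255
    m0 = np.cumsum(hist * np.arange(256))  # background intensity sum
    mu_total = m0[-1] / n
    w1 = n - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (m0[-1] - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2  # ∝ between-class variance
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    # argmax returns the first (smallest) index among exact ties
    return int(np.argmax(sigma_b[:255]))


def binarize(image: np.ndarray, t: float) -> np.ndarray:
    """Foreground = pixel > t (cells are brighter than background after
    stretching); returns a uint8 {0,1} mask."""
    if not (0 <= t <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    return (np.asarray(image) > t).astype(np.uint8)


def remove_small_objects(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Delete every 8-connected component smaller than ``min_area`` pixels."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area == 0:
        return np.asarray(mask, dtype=np.uint8).copy()
    labeled = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labeled].astype(np.uint8)


def dilate(mask: np.ndarray, radius: int = DEFAULT_DILATE_RADIUS) -> np.ndarray:
    """Morphological dilation by a disk; radius 0 is the identity."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    m = np.asarray(mask, dtype=bool)
    if radius == 0:
        return m.astype(np.uint8)
    return ndimage.binary_dilation(m, structure=morphology.disk(radius)).astype(np.uint8)


def label_components(mask: np.ndarray) -> list[Detection]:
    """Label every 8-connected foreground component.

    Detections are ordered by their bounding-box origin (row0, col0); the
    sum of their areas equals the mask's foreground pixel count.
    """
    labeled = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    dets = []
    for rp in measure.regionprops(labeled):
        r0, c0, r1, c1 = rp.bbox
        dets.append(
            Detection(
                label=int(rp.label),
                area=int(rp.area),
                bbox=(int(r0), int(c0), int(r1 - r0), int(c1 - c0)),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    dets.sort(key=lambda d: (d.bbox[0], d.bbox[1], d.label))
    return dets


def segment_frame(
    image: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    dilate_radius: int = DEFAULT_DILATE_RADIUS,
    invert: bool = False,
) -> tuple[np.ndarray, list[Detection]]:
    """Otsu -> binarize -> remove small objects -> dilate -> label.

    ``invert`` flips the polarity for dark-cell imagery.  Returns the final
    mask and its detections.
    """
    img = np.asarray(image)
    if invert:
        img = 255 - img
    t = otsu_threshold(img)
    mask = binarize(img, t)
    mask = remove_small_objects(mask, min_area)
    mask = dilate(mask, dilate_radius)
    return mask, label_components(mask)
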