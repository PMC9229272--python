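"""Shading removal and contrast enhancement.

Raw micrographs of the chip have dark vignetted corners and low
cell/background contrast; both must be fixed before global thresholding or
corner background pixels binarize as spurious foreground.  Two shading
routes are provided:

* ``gamma`` (default) — a concave tone curve I -> I^gamma (gamma < 1)
  brightens the dark corners relative to the center.  Fast, parameter-one.
* ``entropy`` — fits an explicit multiplicative radial gain field by
  minimizing the Shannon entropy of the log-luminance histogram of the
  corrected image; a flat-field image has the most concentrated histogram,
  so entropy is lowest when the shading is undone.  Slower but recovers the
  actual gain.

Contrast is then stretched either to a target interval (min-max) or with a
three-segment piecewise-linear curve expanding a grey band of interest.

All point operations accept uint8 or float input and return float arrays
clipped to [0, 255]; quantization to 8-bit happens once, at the end of
:func:`preprocess_frame`, so chained enhancements are not double-rounded.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .datatypes import StretchParams

__all__ = [
    "to_grayscale",
    "log_luminance_map",
    "estimate_vignette_gain",
    "correct_vignette",
    "gamma_correct",
    "piecewise_linear_stretch",
    "minmax_stretch",
    "preprocess_frame",
    "VignetteFitError",
]

#: default gamma: strong enough brightening that a ~35% quadratic corner
#: falloff on a bright-center field loses at least half its background
#: standard deviation (the std ratio scales like gamma*(255/B)^(1-gamma))
DEFAULT_GAMMA = 0.3


class VignetteFitError(RuntimeError):
    """Entropy minimization failed to converge; ``best_gain`` carries the
    best candidate found."""

    def __init__(self, message: str, best_gain: np.ndarray):
        super().__init__(message)
        self.best_gain = best_gain


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return img


def _to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) color image by the Rec. 601 luma weights;
    grayscale input passes through unchanged."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        luma = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
        return _to_uint8(luma)
    raise ValueError(f"cannot interpret image of shape {arr.shape} as grayscale")


def log_luminance_map(image: np.ndarray, N: int = 256) -> np.ndarray:
    """Logarithmic luminance mapping i(L) = (N-1) * log(1+L) / log(256).

    The log base cancels in the ratio; the endpoints are fixed (0 -> 0 and
    255 -> N-1 for N = 256).  Output is float, clipped to [0, N-1].
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    img = _as_float(image)
    out = (N - 1) * np.log1p(img) / np.log(256.0)
    return np.clip(out, 0, N - 1)


def _radial_coords(shape: tuple[int, int]) -> np.ndarray:
    """Squared radius normalized so the corner distance is 1."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cr, ccol = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return ((rr - cr) ** 2 + (cc - ccol) ** 2) / (cr**2 + ccol**2)


def _gain_from_coeffs(coeffs: np.ndarray, rho2: np.ndarray) -> np.ndarray:
    """g = 1 + c1*rho^2 + c2*rho^4 + ... (even radial powers, g >= 1)."""
    g = np.ones_like(rho2)
    term = np.ones_like(rho2)
    for c in coeffs:
        term = term * rho2
        g = g + c * term
    return g


def _log_histogram_entropy(image: np.ndarray) -> float:
    """Shannon entropy (nats) of the unit-width-bin histogram of the
    log-luminance image — the objective the shading fit minimizes.

    Intensities are NOT clipped and the bins have fixed width, so a uniform
    gain only shifts the log histogram (leaving the entropy unchanged)
    while genuine flattening narrows it; this removes the degenerate
    minimum where an absurd gain saturates every pixel.
    """
    img = np.asarray(image, dtype=float)
    logged = 255.0 * np.log1p(np.clip(img, 0, None)) / np.log(256.0)
    n_bins = max(256, int(np.ceil(logged.max())) + 1)
    hist, _ = np.histogram(logged, bins=n_bins, range=(0, n_bins))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log(p)).sum())


def estimate_vignette_gain(
    image: np.ndarray, model_order: int = 4, max_coeff: float = 4.0
) -> np.ndarray:
    """Fit a smooth multiplicative gain field g(r) >= 1 undoing radial shading.

    The gain is a polynomial in even powers of the normalized radius up to
    ``model_order``; its coefficients are chosen by a derivative-free
    (Powell) search minimizing the log-luminance histogram entropy of the
    corrected image.  Raises :class:`VignetteFitError` (with the best
    candidate attached) if the optimizer does not converge.
    """
    img = _as_float(image)
    if img.max() == img.min():
        raise ValueError("cannot estimate shading of a constant image")
    if model_order < 2 or model_order % 2:
        raise ValueError("model_order must be an even integer >= 2")
    rho2 = _radial_coords(img.shape)
    n_coeff = model_order // 2

    def objective(coeffs: np.ndarray) -> float:
        # keep the gain >= 1 and bounded; smooth finite penalty outside
        violation = float(np.clip(-coeffs, 0, None).sum() + max(coeffs.sum() - max_coeff, 0.0))
        if violation > 0:
            return 50.0 + 100.0 * violation
        return _log_histogram_entropy(img * _gain_from_coeffs(coeffs, rho2))

    res = optimize.minimize(
        objective,
        x0=np.zeros(n_coeff),
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-4, "maxiter": 200},
    )
    gain = _gain_from_coeffs(np.maximum(res.x, 0.0), rho2)
    if not res.success:
        raise VignetteFitError(f"entropy minimization did not converge: {res.message}", gain)
    return gain


def correct_vignette(image: np.ndarray, gain: np.ndarray) -> np.ndarray:
    """Apply a multiplicative gain field; result clipped to [0, 255]."""
    img = _as_float(image)
    gain = np.asarray(gain, dtype=float)
    if gain.shape != img.shape:
        raise ValueError("gain field shape must match the image")
    if np.any(gain <= 0):
        raise ValueError("gain must be strictly positive")
    return np.clip(img * gain, 0.0, 255.0)


def gamma_correct(image: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Power-law tone curve on intensities normalized to [0, 1].

    gamma < 1 brightens dark regions (enhancing low-grey contrast, which is
    what removes dark corners); gamma > 1 is the converse.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = _as_float(image)
    return np.clip(255.0 * (img / 255.0) ** gamma, 0.0, 255.0)


def piecewise_linear_stretch(image: np.ndarray, params: StretchParams) -> np.ndarray:
    """Three-segment grey stretch expanding the band [a, b] of interest.

    Maps [0,a] -> [0,y_a], [a,b] -> [y_a,y_b], [b,M_f] -> [y_b,M_f] with
    straight segments, continuous at the breakpoints and monotone
    non-decreasing for any valid params.
    """
    img = _as_float(image)
    xp = [0.0, params.a, params.b, params.M_f]
    fp = [0.0, params.y_a, params.y_b, params.M_f]
    return np.clip(np.interp(img, xp, fp), 0.0, params.M_f)


def minmax_stretch(image: np.ndarray, MIN: float = 0.0, MAX: float = 255.0) -> np.ndarray:
    """Linear stretch of the image's own grey range onto [MIN, MAX]:
    I' = (I - I_min) / (I_max - I_min) * (MAX - MIN) + MIN."""
    if MIN >= MAX:
        raise ValueError("require MIN < MAX")
    img = _as_float(image)
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise ValueError("constant image has no grey range to stretch")
    return np.clip((img - lo) / (hi - lo) * (MAX - MIN) + MIN, 0.0, 255.0)


def preprocess_frame(
    image: np.ndarray,
    vignette: str = "gamma",
    gamma: float = DEFAULT_GAMMA,
    stretch: str = "minmax",
    stretch_params: StretchParams | None = None,
    stretch_min: float = 0.0,
    stretch_max: float = 255.0,
    gain: np.ndarray | None = None,
) -> np.ndarray:
    """Standard per-frame chain: grayscale -> shading removal -> stretch.

    ``vignette`` is one of ``gamma`` (default), ``entropy`` (uses ``gain``
    if already estimated, else fits it on this frame), or ``none``.
    ``stretch`` is ``minmax`` (default), ``piecewise`` or ``none``.
    """
    img = to_grayscale(image)
    if vignette == "gamma":
        img = gamma_correct(img, gamma)
    elif vignette == "entropy":
        if gain is None:
            gain = estimate_vignette_gain(img)
        img = correct_vignette(img, gain)
    elif vignette != "none":
        raise ValueError(f"unknown vignette mode {vignette!r}")
    if stretch == "minmax":
        img = minmax_stretch(img, stretch_min, stretch_max)
    elif stretch == "piecewise":
        if stretch_params is None:
            raise ValueError("piecewise stretch requires stretch_params")
        img = piecewise_linear_stretch(img, stretch_params)
    elif stretch != "none":
        raise ValueError(f"unknown stretch mode {stretch!r}")
    return _to_uint8(img)
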