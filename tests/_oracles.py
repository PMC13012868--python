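"""Independent brute-force oracles used to validate the image operators.

Everything here is deliberately naive (level-set enumeration, explicit
structuring elements, plain summation) and shares no code path with the
package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EIGHT = np.ones((3, 3), dtype=int)


def area_open_bruteforce(image: np.ndarray, area_threshold: int) -> np.ndarray:
    """Level-set definition of grayscale area opening (8-connectivity).

    out[p] = max{ t : p in a connected component of {image >= t} with
    at least ``area_threshold`` pixels }, enumerated over every intensity
    level present in the image.  Integer-valued images only.
    """
    image = np.asarray(image)
    out = np.zeros_like(image)
    for t in np.unique(image):
        if t <= 0:
            continue
        labels, n = ndimage.label(image >= t, structure=EIGHT)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.isin(labels, np.nonzero(sizes >= area_threshold)[0] + 1)
        out = np.where(keep, np.maximum(out, t), out)
    return out


def granulometry_losses_bruteforce(image: np.ndarray, area_thresholds) -> np.ndarray:
    """Per-bin intensity losses from brute-force openings of the *original*
    image at each successive threshold."""
    prev = np.asarray(image)
    losses = []
    for a in area_thresholds:
        opened = area_open_bruteforce(image, int(np.ceil(a - 1e-9)))
        losses.append(float(prev.sum() - opened.sum()))
        prev = opened
    return np.array(losses)


def ball_structure(radius: float) -> np.ndarray:
    """Non-flat ball structuring element: height of the ball surface above
    its lowest point, -inf outside the ball's footprint."""
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    s = np.full(d2.shape, -np.inf)
    inside = d2 <= radius**2
    s[inside] = np.sqrt(radius**2 - d2[inside])
    return s


def rolling_ball_background_oracle(image: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background as grayscale opening with a ball structuring
    element: erosion then dilation with the ball's height profile."""
    s = ball_structure(radius)
    footprint = np.isfinite(s)
    heights = np.where(footprint, s, 0.0)
    eroded = ndimage.grey_erosion(image, footprint=footprint, structure=heights)
    return ndimage.grey_dilation(eroded, footprint=footprint, structure=heights)


def moments_direct(x, y, dx) -> tuple[float, float, float, float]:
    """Plain-Python direct summation of the four discrete moments."""
    mu = sum(xi * yi * dx for xi, yi in zip(x, y))
    var = sum((xi - mu) ** 2 * yi * dx for xi, yi in zip(x, y))
    sigma = var**0.5
    skew = sum(((xi - mu) ** 3 / sigma**3) * yi * dx for xi, yi in zip(x, y))
    kurt = sum(((xi - mu) ** 4 / sigma**4) * yi * dx for xi, yi in zip(x, y))
    return mu, var, skew, kurt
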