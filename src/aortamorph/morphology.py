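"""Euclidean-ball morphology on boolean volumes.

Every "distance = n voxels" operation in the workflow uses a Euclidean
ball of radius n, realized by thresholding an exact Euclidean distance
transform.  This is equivalent to dilation/erosion with an explicit ball
structuring element ``{o : |o| <= n}`` but scales better with radius.

Outside the array, background is assumed (masks are expected not to touch
the border; :func:`ball_close` pads internally so dilation is never
clipped).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "ball",
    "ball_dilate",
    "ball_erode",
    "ball_open",
    "ball_close",
    "disc_erode",
]


def ball(radius: float, ndim: int = 3) -> np.ndarray:
    """Boolean Euclidean ball structuring element of the given radius."""
    r = int(np.floor(radius))
    grids = np.ogrid[tuple(slice(-r, r + 1) for _ in range(ndim))]
    return sum(g * g for g in grids) <= radius * radius


def ball_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilate by a Euclidean ball: voxels within ``radius`` of the mask."""
    if radius <= 0 or not mask.any():
        return mask.copy()
    pad = int(np.floor(radius)) + 1
    padded = np.pad(mask, pad)
    dist = ndimage.distance_transform_edt(~padded)
    out = dist <= radius
    sl = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    return out[sl]


def ball_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erode by a Euclidean ball; outside the array counts as background."""
    if radius <= 0:
        return mask.copy()
    padded = np.pad(mask, 1)  # border is background
    dist = ndimage.distance_transform_edt(padded)
    out = dist > radius
    sl = tuple(slice(1, -1) for _ in range(mask.ndim))
    return out[sl]


def ball_open(mask: np.ndarray, radius: float) -> np.ndarray:
    return ball_dilate(ball_erode(mask, radius), radius)


def ball_close(mask: np.ndarray, radius: float) -> np.ndarray:
    """Closing computed in a padded box so it is not clipped at borders."""
    if radius <= 0 or not mask.any():
        return mask.copy()
    pad = int(np.ceil(radius)) + 2
    padded = np.pad(mask, pad)
    closed = ball_erode(ball_dilate(padded, radius), radius)
    sl = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    return closed[sl]


def disc_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    """Slice-wise in-plane erosion of a 3-D mask by a Euclidean disc.

    Used for the ROI shell: the ROI is defined per axial slice by the
    contouring process, so its inward erosion is an in-plane operation
    (a 3-D ball would also erode the first and last contoured slices
    axially, capping the vessel).
    """
    if radius <= 0:
        return mask.copy()
    out = np.empty_like(mask)
    for i in range(mask.shape[0]):
        out[i] = ball_erode(mask[i], radius)
    return out
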