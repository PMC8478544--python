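"""Independent brute-force reference implementations.

Everything here is written the slow, obvious way (explicit loops, BFS,
exhaustive neighborhood scans) and is deliberately independent of the
package's vectorized/distance-transform implementations, so the two can
be compared voxel-exactly on small volumes.
"""

from collections import deque

import numpy as np


def point_in_polygon(point, vertices) -> bool:
    """Ray casting with explicit on-boundary inclusion."""
    x, y = float(point[0]), float(point[1])
    n = len(vertices)
    # boundary check: point on any closed edge segment
    for i in range(n):
        ax, ay = vertices[i]
        bx, by = vertices[(i + 1) % n]
        cross = (bx - ax) * (y - ay) - (by - ay) * (x - ax)
        if abs(cross) < 1e-12:
            if min(ax, bx) - 1e-12 <= x <= max(ax, bx) + 1e-12 and \
               min(ay, by) - 1e-12 <= y <= max(ay, by) + 1e-12:
                return True
    inside = False
    for i in range(n):
        ax, ay = vertices[i]
        bx, by = vertices[(i + 1) % n]
        if (ay > y) != (by > y):
            x_cross = ax + (y - ay) / (by - ay) * (bx - ax)
            if x < x_cross:
                inside = not inside
    return inside


def rasterize_polygon(vertices, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            out[r, c] = point_in_polygon((r, c), vertices)
    return out


def threshold(volume, roi, level) -> np.ndarray:
    out = np.zeros(volume.shape, dtype=bool)
    for idx in np.ndindex(volume.shape):
        out[idx] = roi[idx] and volume[idx] >= level
    return out


def ball_offsets(radius):
    r = int(np.floor(radius))
    offs = []
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dz * dz + dy * dy + dx * dx <= radius * radius:
                    offs.append((dz, dy, dx))
    return offs


def ball_dilate(mask, radius) -> np.ndarray:
    offs = ball_offsets(radius)
    out = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    for z, y, x in zip(*np.nonzero(mask)):
        for dz, dy, dx in offs:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                out[zz, yy, xx] = True
    return out


def ball_erode(mask, radius) -> np.ndarray:
    """Outside the array counts as background."""
    offs = ball_offsets(radius)
    out = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    for z, y, x in zip(*np.nonzero(mask)):
        ok = True
        for dz, dy, dx in offs:
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx) or not mask[zz, yy, xx]:
                ok = False
                break
        out[z, y, x] = ok
    return out


def disc_erode_2d(mask2d, radius) -> np.ndarray:
    """Exhaustive 2-D Euclidean disc erosion; outside counts as background."""
    r = int(np.floor(radius))
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = np.zeros_like(mask2d)
    ny, nx = mask2d.shape
    for y, x in zip(*np.nonzero(mask2d)):
        ok = True
        for dy, dx in offs:
            yy, xx = y + dy, x + dx
            if not (0 <= yy < ny and 0 <= xx < nx) or not mask2d[yy, xx]:
                ok = False
                break
        out[y, x] = ok
    return out


def ball_close_padded(mask, radius) -> np.ndarray:
    pad = int(np.ceil(radius)) + 2
    padded = np.pad(mask, pad)
    closed = ball_erode(ball_dilate(padded, radius), radius)
    sl = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    return closed[sl]


_FACE_NEIGHBORS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def connected_components(mask, connectivity=6):
    """BFS labeling; returns (labels, counts) with labels starting at 1."""
    if connectivity == 6:
        neigh = _FACE_NEIGHBORS
    else:
        neigh = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    labels = np.zeros(mask.shape, dtype=int)
    counts = []
    nz, ny, nx = mask.shape
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        size = 0
        while queue:
            z, y, x = queue.popleft()
            size += 1
            for dz, dy, dx in neigh:
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                    if mask[zz, yy, xx] and not labels[zz, yy, xx]:
                        labels[zz, yy, xx] = next_label
                        queue.append((zz, yy, xx))
        counts.append(size)
    return labels, counts


def largest_cavity(boundary, roi) -> np.ndarray:
    """Flood-fill the complement of the boundary within the ROI, 6-conn."""
    interior = roi & ~boundary
    labels, counts = connected_components(interior, connectivity=6)
    if not counts:
        return np.zeros_like(roi)
    best = int(np.argmax(counts)) + 1
    return labels == best


def component_volume_filter(mask, fraction) -> np.ndarray:
    labels, counts = connected_components(mask, connectivity=26)
    total = sum(counts)
    out = np.zeros_like(mask)
    for lab, size in enumerate(counts, start=1):
        if size >= fraction * total:
            out |= labels == lab
    return out


def gaussian3_smooth(volume, sigma) -> np.ndarray:
    """Direct convolution with a truncated (radius 1), renormalized kernel."""
    t = np.arange(-1, 2)
    k1 = np.exp(-0.5 * (t / sigma) ** 2)
    k1 /= k1.sum()
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    padded = np.pad(volume, 1, mode="edge")
    out = np.zeros_like(volume, dtype=float)
    nz, ny, nx = volume.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                out[z, y, x] = (kernel * padded[z : z + 3, y : y + 3, x : x + 3]).sum()
    return out


def face_adjacent_contact(plaque, wall) -> np.ndarray:
    """Plaque voxels with a wall voxel among their 6 face neighbors."""
    out = np.zeros_like(plaque)
    nz, ny, nx = plaque.shape
    for z, y, x in zip(*np.nonzero(plaque)):
        for dz, dy, dx in _FACE_NEIGHBORS:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and wall[zz, yy, xx]:
                out[z, y, x] = True
                break
    return out


def count_voxels(mask) -> int:
    n = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx]:
            n += 1
    return n
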