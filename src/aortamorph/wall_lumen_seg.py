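"""Automatic aortic wall and lumen segmentation inside the ROI.

The vessel wall of a PTA-stained aorta attenuates strongly, so a fixed
high threshold (6.0 cm^-1) inside the ROI yields a draft of the wall.  The
draft is rarely a closed tube: under-stained wall patches and arterial
branch ostia leave gaps, while highly stained plaque may merge with it.
The draft is therefore closed by overlaying the 2-voxel inner shell of the
ROI (the ROI minus its in-plane erosion), the closed object is inverted,
and the largest interior connected component becomes the lumen draft.
Voids left inside the lumen draft by wall-bright plaque are absorbed by a
5-voxel morphological closing.  Finally the aorta mask is the union of
wall draft and lumen, and the wall mask is the aorta minus the lumen —
which deliberately reassigns wall-bright plaque voxels to the lumen.

All masks obey exact set algebra: ``wall ∩ lumen = ∅`` and
``aorta = wall ∪ lumen`` voxel-wise on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import morphology as morph
from .roi_tools import RoiMask
from .volume_io import BinaryMask, GrayscaleVolume

__all__ = [
    "SegParams",
    "WallLumenResult",
    "MaskEdit",
    "DegenerateRoiError",
    "EmptyLumenError",
    "threshold_wall_draft",
    "build_closed_boundary",
    "extract_lumen_draft",
    "fill_lumen_voids",
    "compose_wall_lumen",
    "segment_wall_lumen",
]


class DegenerateRoiError(ValueError):
    """ROI too thin: the shell erosion emptied a contoured slice."""


class EmptyLumenError(ValueError):
    """No interior component remains after boundary closure."""


@dataclass
class SegParams:
    """All tunable parameters of the segmentation workflow.

    Defaults are the workflow's published operating point for 10 µm
    PTA-stained mouse aorta scans; distances are in voxels, thresholds in
    cm^-1.
    """

    wall_threshold: float = 6.0  # cm^-1, wall/plaque-core draft threshold
    shell_erosion: int = 2  # voxels, inward ROI shell thickness
    lumen_close_distance: int = 5  # voxels, lumen void-filling closing
    plaque_sigma: float = 0.8  # voxels, Gaussian smoothing width
    plaque_support: int = 1  # voxels, Gaussian kernel truncation radius
    plaque_threshold: float = 2.0  # cm^-1, stained-tissue threshold
    opening_distance: int = 1  # voxels, plaque draft opening
    min_component_fraction: float = 0.02  # of post-opening plaque volume
    closing_distance: int = 3  # voxels, plaque draft closing

    def __post_init__(self) -> None:
        for name in ("shell_erosion", "lumen_close_distance", "plaque_support",
                     "opening_distance", "closing_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("wall_threshold", "plaque_threshold", "plaque_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.min_component_fraction <= 1.0:
            raise ValueError("min_component_fraction must be in [0, 1]")


@dataclass
class MaskEdit:
    """Manual lumen correction: voxel patches to add and/or remove."""

    add: np.ndarray | None = None
    remove: np.ndarray | None = None


@dataclass
class WallLumenResult:
    wall_mask: BinaryMask
    lumen_mask: BinaryMask
    aorta_mask: BinaryMask
    intermediate: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w, l, a = self.wall_mask.data, self.lumen_mask.data, self.aorta_mask.data
        if (w & l).any():
            raise ValueError("wall and lumen masks overlap")
        if not np.array_equal(a, w | l):
            raise ValueError("aorta mask must equal wall ∪ lumen exactly")


def _check_grid(a, b, what: str) -> None:
    if not a.same_grid(b):
        raise ValueError(f"grid mismatch between {what}")


def threshold_wall_draft(
    volume: GrayscaleVolume, roi: RoiMask, params: SegParams | None = None
) -> BinaryMask:
    """Fixed high threshold within the ROI (inclusive: >= wall_threshold)."""
    params = params or SegParams()
    _check_grid(volume, roi, "volume and ROI")
    draft = roi.data & (volume.data >= params.wall_threshold)
    return BinaryMask(draft, volume.voxel_size, "wall_draft", volume.origin)


def build_closed_boundary(
    wall_draft: BinaryMask, roi: RoiMask, params: SegParams | None = None
) -> BinaryMask:
    """Close the wall draft with the inner shell of the ROI.

    shell = roi \\ erode(roi, shell_erosion), eroded in-plane per slice;
    the union of draft and shell bounds the lumen even across branch
    ostia and under-stained wall.
    """
    params = params or SegParams()
    _check_grid(wall_draft, roi, "wall draft and ROI")
    eroded = morph.disc_erode(roi.data, params.shell_erosion)
    roi_any = roi.data.any(axis=(1, 2))
    emptied = roi_any & ~eroded.any(axis=(1, 2))
    if emptied.any():
        bad = int(np.flatnonzero(emptied)[0])
        raise DegenerateRoiError(
            f"shell erosion ({params.shell_erosion} voxels) emptied ROI slice {bad}"
        )
    shell = roi.data & ~eroded
    return BinaryMask(wall_draft.data | shell, roi.voxel_size, "wall_draft", roi.origin)


def extract_lumen_draft(closed_boundary: BinaryMask, roi: RoiMask) -> BinaryMask:
    """Invert the closed boundary within the ROI; keep the largest cavity.

    Connected components use 6-connectivity; ties go to the component
    first encountered in raster order.
    """
    _check_grid(closed_boundary, roi, "closed boundary and ROI")
    if (closed_boundary.data & ~roi.data).any():
        raise ValueError("closed boundary must be contained in the ROI")
    interior = roi.data & ~closed_boundary.data
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(interior, structure=structure)
    if n == 0:
        raise EmptyLumenError("boundary closure left no interior component")
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns the lowest label on ties
    return BinaryMask(labels == best, roi.voxel_size, "lumen_draft", roi.origin)


def fill_lumen_voids(lumen_draft: BinaryMask, params: SegParams | None = None) -> BinaryMask:
    """Absorb plaque-shaped voids via a Euclidean-ball closing.

    Computed in a padded bounding box so the closing is never clipped at
    array borders.
    """
    params = params or SegParams()
    closed = morph.ball_close(lumen_draft.data, params.lumen_close_distance)
    return BinaryMask(closed, lumen_draft.voxel_size, "lumen", lumen_draft.origin)


def compose_wall_lumen(wall_draft: BinaryMask, lumen: BinaryMask) -> WallLumenResult:
    """aorta = wall_draft ∪ lumen; wall = aorta \\ lumen.

    Voxels claimed by both (wall-bright plaque) are assigned to the lumen.
    """
    _check_grid(wall_draft, lumen, "wall draft and lumen")
    aorta = wall_draft.data | lumen.data
    wall = aorta & ~lumen.data
    vs, org = lumen.voxel_size, lumen.origin
    return WallLumenResult(
        wall_mask=BinaryMask(wall, vs, "wall", org),
        lumen_mask=BinaryMask(lumen.data.copy(), vs, "lumen", org),
        aorta_mask=BinaryMask(aorta, vs, "aorta", org),
    )


def segment_wall_lumen(
    volume: GrayscaleVolume,
    roi: RoiMask,
    params: SegParams | None = None,
    manual_lumen_edits: MaskEdit | None = None,
    keep_intermediates: bool = False,
) -> WallLumenResult:
    """Full wall/lumen chain: threshold → close → invert → fill → compose.

    The filled lumen is constrained to the ROI interior (inside the
    shell), so it can never touch the ROI border.  Optional manual edits
    are applied to the lumen between void-filling and composition;
    additions are clipped to the ROI interior to preserve containment.
    """
    params = params or SegParams()
    draft = threshold_wall_draft(volume, roi, params)
    boundary = build_closed_boundary(draft, roi, params)
    lumen_draft = extract_lumen_draft(boundary, roi)
    lumen = fill_lumen_voids(lumen_draft, params)

    interior = morph.disc_erode(roi.data, params.shell_erosion)
    lumen_data = lumen.data & interior
    if manual_lumen_edits is not None:
        if manual_lumen_edits.add is not None:
            lumen_data |= np.asarray(manual_lumen_edits.add, bool) & interior
        if manual_lumen_edits.remove is not None:
            lumen_data &= ~np.asarray(manual_lumen_edits.remove, bool)
    lumen = BinaryMask(lumen_data, lumen.voxel_size, "lumen", lumen.origin)

    result = compose_wall_lumen(draft, lumen)
    if keep_intermediates:
        result.intermediate = {
            "wall_draft": draft,
            "shell": BinaryMask(boundary.data & ~draft.data, roi.voxel_size, "wall_draft", roi.origin),
            "closed_boundary": boundary,
            "lumen_draft": lumen_draft,
        }
    return result
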