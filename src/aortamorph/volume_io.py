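"""Volume, mask, contour and mesh I/O.

This module fixes the grid and unit conventions every other module relies
on:

* A volume is a 3-D scalar field of linear attenuation in cm^-1 sampled on
  an isotropic voxel grid.  Axis 0 is the axial (cranio-caudal) axis; a
  "slice" is always a plane perpendicular to axis 0.
* Voxel indices are 0-based; the physical position of a voxel center is
  ``index * voxel_size + origin`` with ``voxel_size`` in mm/voxel.
* Attenuation calibration happens in exactly one place: the ``units_scale``
  argument of :func:`read_volume`.  Everything downstream assumes cm^-1.

Supported containers: NIfTI (``.nii``/``.nii.gz``) single-file volumes,
single multi-page TIFF files, and directories of equally sized 2-D TIFF/PNG
slices in lexicographic order.  Masks are stored as 8-bit 0/255 volumes in
the same containers with a JSON sidecar carrying the role label and grid
metadata.  Meshes are written as STL or PLY with vertices in mm.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MASK_ROLES",
    "GrayscaleVolume",
    "BinaryMask",
    "ContourSet",
    "FormatError",
    "ConfigurationError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "export_mesh",
    "read_contours",
    "write_contours",
]

#: Roles a binary mask may take inside the segmentation workflow.
MASK_ROLES = frozenset(
    {
        "roi",
        "wall_draft",
        "lumen_draft",
        "lumen",
        "wall",
        "aorta",
        "plaque_draft",
        "plaque",
        "lesion",
    }
)


class FormatError(ValueError):
    """Raised when a file on disk does not satisfy the format contract."""


class ConfigurationError(ValueError):
    """Raised when required metadata (e.g. voxel size) is missing."""


def _as_origin(origin) -> np.ndarray:
    out = np.zeros(3, dtype=float) if origin is None else np.asarray(origin, dtype=float)
    if out.shape != (3,):
        raise ValueError(f"origin must be a 3-vector, got shape {out.shape}")
    return out


@dataclass
class GrayscaleVolume:
    """3-D field of linear attenuation (cm^-1) on an isotropic voxel grid.

    Parameters
    ----------
    data
        3-D float array of attenuation values; must be finite.
    voxel_size
        Edge length of the (isotropic) voxel in mm.
    origin
        Physical position in mm of the voxel at index ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D with all dims >= 1, got shape {self.data.shape}")
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("attenuation values must be finite (no NaN/Inf)")
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "GrayscaleVolume | BinaryMask") -> bool:
        return self.shape == other.shape and np.isclose(self.voxel_size, other.voxel_size)


@dataclass
class BinaryMask:
    """Boolean 3-D field on the grid of its parent volume.

    ``role`` records which segmentation object the mask represents and must
    be one of :data:`MASK_ROLES`.
    """

    data: np.ndarray
    voxel_size: float
    role: str
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"mask must be 3-D with all dims >= 1, got shape {self.data.shape}")
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {sorted(MASK_ROLES)}")
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        """Number of set voxels."""
        return int(self.data.sum())

    def same_grid(self, other: "GrayscaleVolume | BinaryMask") -> bool:
        return self.shape == other.shape and np.isclose(self.voxel_size, other.voxel_size)

    def with_role(self, role: str) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.voxel_size, role, self.origin.copy())


@dataclass
class ContourSet:
    """Sparse per-slice closed polygons of the outer aortic boundary.

    ``contours`` is an ordered list of ``(slice_index, vertices)`` pairs
    where ``vertices`` is an ``(n, 2)`` array of in-plane ``(row, col)``
    coordinates (axis-1, axis-2 of the volume).  The polygon is implicitly
    closed: the last vertex connects back to the first.  Coordinates are
    either voxel indices (``units='voxel'``) or mm (``units='mm'``).
    """

    contours: list[tuple[int, np.ndarray]]
    units: str = "voxel"

    def __post_init__(self) -> None:
        if self.units not in {"voxel", "mm"}:
            raise ValueError(f"units must be 'voxel' or 'mm', got {self.units!r}")
        cleaned: list[tuple[int, np.ndarray]] = []
        prev = None
        for idx, verts in self.contours:
            idx = int(idx)
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError(f"contour on slice {idx} needs an (n>=3, 2) vertex array")
            if prev is not None and idx <= prev:
                raise ValueError("contour slice indices must be strictly increasing")
            prev = idx
            cleaned.append((idx, verts))
        if not cleaned:
            raise ValueError("ContourSet needs at least one contour")
        self.contours = cleaned

    @property
    def slice_indices(self) -> list[int]:
        return [idx for idx, _ in self.contours]

    def to_voxel(self, voxel_size: float, origin: Sequence[float] = (0.0, 0.0, 0.0)) -> "ContourSet":
        """Convert mm coordinates to voxel indices on the given grid."""
        if self.units == "voxel":
            return self
        oy, ox = float(origin[1]), float(origin[2])
        conv = [
            (idx, (verts - np.array([oy, ox])) / voxel_size)
            for idx, verts in self.contours
        ]
        return ContourSet(conv, units="voxel")


# ---------------------------------------------------------------------------
# volumes


_STACK_EXTS = {".tif", ".tiff", ".png"}


def _read_array(path: Path) -> tuple[np.ndarray, float | None]:
    """Read a 3-D array plus voxel size (mm) if the container stores one."""
    import nibabel as nib
    import tifffile

    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D NIfTI volume, got ndim={data.ndim}")
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-3):
            raise FormatError(f"{path}: anisotropic voxels {zooms} are not supported")
        # nibabel stores (x, y, z); our convention is (axial, row, col)
        return np.transpose(data, (2, 1, 0)), float(zooms[0])
    if name.endswith((".tif", ".tiff")):
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a multi-page TIFF stack, got ndim={data.ndim}")
        return data, None
    raise FormatError(f"{path}: unrecognized volume format")


def _read_stack_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _STACK_EXTS)
    if not files:
        raise FormatError(f"{path}: no slice images found")
    slices = []
    for p in files:
        arr = iio.imread(p)
        if arr.ndim != 2:
            raise FormatError(f"{p}: slice images must be single-channel 2-D")
        if slices and arr.shape != slices[0].shape:
            raise FormatError(
                f"{p}: inconsistent slice shape {arr.shape} vs {slices[0].shape}"
            )
        slices.append(arr)
    return np.stack(slices, axis=0)


def read_volume(
    path: str | os.PathLike,
    units_scale: float = 1.0,
    voxel_size_override: float | None = None,
    origin: Sequence[float] | None = None,
) -> GrayscaleVolume:
    """Load a grayscale volume and calibrate it to cm^-1.

    Parameters
    ----------
    path
        Single-file volume (NIfTI, multi-page TIFF) or a directory of
        equally sized 2-D slice images read in lexicographic order.
    units_scale
        Multiplier applied to the stored values so that the result is in
        cm^-1 (e.g. ``0.001`` for a scanner that stores milli-units as
        16-bit integers).  This is the only calibration point in the
        package.
    voxel_size_override
        Voxel edge length in mm; required when the container does not
        store one (TIFF), overrides the header when it does.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    if p.is_dir():
        data, meta_vs = _read_stack_dir(p), None
    else:
        data, meta_vs = _read_array(p)
    voxel_size = voxel_size_override if voxel_size_override is not None else meta_vs
    if voxel_size is None:
        raise ConfigurationError(
            f"{p}: container stores no voxel size; pass voxel_size_override (mm)"
        )
    data = np.asarray(data, dtype=np.float64) * float(units_scale)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{p}: volume contains non-finite values after loading")
    return GrayscaleVolume(data, float(voxel_size), _as_origin(origin))


def write_volume(volume: GrayscaleVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI or multi-page TIFF (by extension), float64."""
    import nibabel as nib
    import tifffile

    p = Path(path)
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag([volume.voxel_size] * 3 + [1.0])
        affine[:3, 3] = volume.origin[::-1]
        img = nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)), affine)
        img.header.set_zooms((volume.voxel_size,) * 3)
        nib.save(img, str(p))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(p), volume.data, photometric="minisblack")
        _write_sidecar(p, {"voxel_size_mm": volume.voxel_size, "origin_mm": volume.origin.tolist()})
    else:
        raise FormatError(f"{p}: unrecognized volume format for writing")


# ---------------------------------------------------------------------------
# masks


def _sidecar_path(p: Path) -> Path:
    return p.with_name(p.name + ".json")


def _write_sidecar(p: Path, payload: dict) -> None:
    _sidecar_path(p).write_text(json.dumps(payload, indent=2))


def _read_sidecar(p: Path) -> dict:
    sp = _sidecar_path(p)
    return json.loads(sp.read_text()) if sp.exists() else {}


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as an 8-bit 0/255 volume plus a JSON metadata sidecar."""
    import nibabel as nib
    import tifffile

    p = Path(path)
    arr = mask.data.astype(np.uint8) * 255
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag([mask.voxel_size] * 3 + [1.0])
        affine[:3, 3] = mask.origin[::-1]
        nib.save(nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine), str(p))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(p), arr, photometric="minisblack")
    else:
        raise FormatError(f"{p}: unrecognized mask format for writing")
    _write_sidecar(
        p,
        {
            "role": mask.role,
            "voxel_size_mm": mask.voxel_size,
            "origin_mm": mask.origin.tolist(),
        },
    )


def read_mask(
    path: str | os.PathLike,
    role: str | None = None,
    voxel_size_override: float | None = None,
) -> BinaryMask:
    """Read a 0/255 mask volume; role/grid come from the sidecar unless given."""
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file: {p}")
    data, meta_vs = _read_array(p)
    meta = _read_sidecar(p)
    voxel_size = voxel_size_override or meta.get("voxel_size_mm") or meta_vs
    if voxel_size is None:
        raise ConfigurationError(f"{p}: no voxel size in sidecar or header")
    role = role or meta.get("role")
    if role is None:
        raise ConfigurationError(f"{p}: mask role not recorded; pass role=")
    origin = np.asarray(meta.get("origin_mm", (0.0, 0.0, 0.0)), dtype=float)
    return BinaryMask(data > 0, float(voxel_size), role, origin)


# ---------------------------------------------------------------------------
# meshes


def mask_to_mesh(mask: BinaryMask):
    """Triangulate the 0.5 iso-surface of a mask; vertices in mm.

    The binary field is padded with one layer of background so the surface
    is closed even when the mask touches the array border.
    """
    import trimesh
    from skimage import measure

    if mask.count() == 0:
        raise ValueError("cannot triangulate an empty mask")
    padded = np.pad(mask.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * mask.voxel_size + mask.origin
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def export_mesh(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write the triangulated mask boundary as STL or PLY (by extension)."""
    p = Path(path)
    mesh = mask_to_mesh(mask)
    ext = p.suffix.lower().lstrip(".")
    if ext not in {"stl", "ply"}:
        raise FormatError(f"{p}: mesh format must be .stl or .ply")
    mesh.export(str(p))


# ---------------------------------------------------------------------------
# contours
#
# Contour file schema (plain text, '#' comments allowed):
#
#     units voxel            # or: units mm
#     slice 12
#     10.0 14.5              # row col, one vertex per line
#     ...
#     slice 40
#     ...


def write_contours(contours: ContourSet, path: str | os.PathLike) -> None:
    lines = [f"units {contours.units}"]
    for idx, verts in contours.contours:
        lines.append(f"slice {idx}")
        lines.extend(f"{r:.6g} {c:.6g}" for r, c in verts)
    Path(path).write_text("\n".join(lines) + "\n")


def read_contours(path: str | os.PathLike) -> ContourSet:
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such contour file: {p}")
    units = "voxel"
    contours: list[tuple[int, list[list[float]]]] = []
    for lineno, raw in enumerate(p.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "units":
            units = parts[1]
        elif parts[0] == "slice":
            contours.append((int(parts[1]), []))
        else:
            if not contours:
                raise FormatError(f"{p}:{lineno}: vertex before any 'slice' header")
            if len(parts) != 2:
                raise FormatError(f"{p}:{lineno}: expected 'row col'")
            contours[-1][1].append([float(parts[0]), float(parts[1])])
    return ContourSet([(i, np.asarray(v)) for i, v in contours], units=units)
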