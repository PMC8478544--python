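"""Synthetic contrast-enhanced aorta phantoms with analytic ground truth.

A phantom is a tube (straight or circular-arc centerline) with a
high-attenuation wall, low-attenuation lumen/background, and optional
plaques: circular-segment prisms attached to the inner wall (the region
of the lumen cross-section cut off by a chord at depth ``d`` from the
wall, oriented at a chosen angle).  Optional branch gaps cut wedge-shaped
holes in the wall, emulating arterial ostia.  Partial-volume blur is
emulated by Gaussian smoothing of the crisp attenuation classes, plus
additive Gaussian noise.

Ground truth is the *pre-blur* crisp geometry, so measured recovery error
honestly includes partial-volume effects.  Analytic volumes are exact:
``pi r^2 L`` for the lumen along the centerline length, the circular
segment area times span for straight plaques, and the Pappus rule
(segment area times centroid path length) for plaques on arc centerlines.

Default attenuations (lumen 0.5, plaque 3.5, wall 8.0 cm^-1) straddle the
two workflow thresholds (2.0, 6.0 cm^-1); they are synthetic fixture
constants, not measured PTA values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import morphology as morph
from .volume_io import BinaryMask, ContourSet, GrayscaleVolume

__all__ = [
    "PlaqueSpec",
    "BranchGap",
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "phantom_contours",
    "phantom_suite",
    "SUITE_LEVELS",
]


@dataclass
class PlaqueSpec:
    """Circular-segment plaque attached to the inner wall.

    ``angle_deg`` is the angular position around the vessel axis (0 =
    reference direction; for arc centerlines 0 points away from the arc
    center).  The plaque occupies the lumen region beyond a chord at
    ``depth_mm`` from the wall, over an axial (arc-length) span.  If
    ``core_attenuation`` is set, the plaque interior eroded by
    ``core_margin_voxels`` takes that value — used to emulate heavily
    stained plaque cores that threshold like wall.
    """

    angle_deg: float
    axial_center_mm: float
    axial_span_mm: float
    depth_mm: float
    attenuation: float = 3.5
    core_attenuation: float | None = None
    core_margin_voxels: float = 2.0


@dataclass
class BranchGap:
    """Wedge-shaped wall discontinuity emulating a branch ostium."""

    axial_center_mm: float
    angular_span_deg: float
    angle_deg: float = 0.0
    axial_extent_mm: float = 0.2


@dataclass
class PhantomSpec:
    """Parametric synthetic aorta.  All lengths mm, attenuations cm^-1."""

    shape: tuple[int, int, int] = (120, 64, 64)
    voxel_size: float = 0.01
    centerline: str = "straight"  # "straight" | "arc"
    arc_radius: float = 2.0  # mm, only for centerline="arc"
    lumen_radius: float = 0.143
    wall_thickness: float = 0.041
    wall_attenuation: float = 8.0
    lumen_attenuation: float = 0.5
    plaques: list[PlaqueSpec] = field(default_factory=list)
    branch_gaps: list[BranchGap] = field(default_factory=list)
    blur_sigma: float = 0.0  # voxels
    noise_sd: float = 0.0  # cm^-1
    seed: int = 0
    axial_margin: float = 0.08  # mm kept free at both axial ends

    def __post_init__(self) -> None:
        if self.lumen_radius <= 0 or self.wall_thickness <= 0:
            raise ValueError("lumen_radius and wall_thickness must be > 0")
        if self.centerline not in {"straight", "arc"}:
            raise ValueError("centerline must be 'straight' or 'arc'")
        for p in self.plaques:
            if not 0 < p.depth_mm < self.lumen_radius:
                raise ValueError("plaque depth must be in (0, lumen_radius)")
        r_need = self.lumen_radius + self.wall_thickness
        half_y = self.shape[1] * self.voxel_size / 2
        half_x = self.shape[2] * self.voxel_size / 2
        if r_need >= min(half_y, half_x):
            raise ValueError("tube does not fit the in-plane grid extent")

    @property
    def tube_length(self) -> float:
        """Centerline arc length within the axial span, mm."""
        z_extent = self.shape[0] * self.voxel_size - 2 * self.axial_margin
        if self.centerline == "straight":
            return z_extent
        psi = np.arcsin(z_extent / 2 / self.arc_radius)
        return 2 * psi * self.arc_radius


@dataclass
class PhantomGroundTruth:
    """Pre-blur rasterized masks plus closed-form reference values."""

    wall: BinaryMask
    lumen: BinaryMask
    plaque: BinaryMask
    lesion: BinaryMask
    analytic_lumen_volume: float  # mm^3
    analytic_plaque_volume: float  # mm^3
    analytic_wall_thickness: float  # mm


def _segment_geometry(radius: float, depth: float) -> tuple[float, float]:
    """Area and centroid offset (from circle center) of a circular segment."""
    alpha = 2.0 * np.arccos((radius - depth) / radius)
    area = 0.5 * radius**2 * (alpha - np.sin(alpha))
    centroid = 4.0 * radius * np.sin(alpha / 2.0) ** 3 / (3.0 * (alpha - np.sin(alpha)))
    return area, centroid


def _tube_center(spec: PhantomSpec) -> tuple[float, float]:
    """In-plane tube center in mm, deliberately off the voxel lattice.

    Real vessels never align with the reconstruction grid; a lattice-
    aligned center (with round radii) would place material interfaces
    exactly on voxel centers and alias the rasterized volumes by several
    percent.  The fractional offsets keep interfaces off-lattice.
    """
    _, ny, nx = spec.shape
    return (ny / 2 + 0.31) * spec.voxel_size, (nx / 2 + 0.17) * spec.voxel_size


def _local_frame(spec: PhantomSpec):
    """Per-voxel tube coordinates: radius rho, angle phi, arc length s.

    ``s`` is NaN outside the axial span.  ``phi=0`` is the +y direction
    for straight tubes and the direction away from the arc center for arc
    tubes.  Returns (rho, phi, s, length).
    """
    nz, ny, nx = spec.shape
    vs = spec.voxel_size
    z = np.arange(nz)[:, None, None] * vs
    y = np.arange(ny)[None, :, None] * vs
    x = np.arange(nx)[None, None, :] * vs
    cy, cx = _tube_center(spec)
    z_lo, z_hi = spec.axial_margin, nz * vs - spec.axial_margin

    if spec.centerline == "straight":
        rho = np.sqrt((y - cy) ** 2 + (x - cx) ** 2) + 0 * z
        phi = np.arctan2(x - cx, y - cy) + 0 * z
        s = np.where((z >= z_lo) & (z <= z_hi), z - z_lo, np.nan) + 0 * y + 0 * x
        return rho, phi, s, z_hi - z_lo

    rc = spec.arc_radius
    z_mid = nz * vs / 2
    psi_max = np.arcsin((z_hi - z_lo) / 2 / rc)
    # arc center sits beyond the tube in +y; apex of the arc at (z_mid, cy)
    c_z, c_y = z_mid, cy + rc
    u_z, u_y = z - c_z, y - c_y
    dist_c = np.sqrt(u_z**2 + u_y**2) + 0 * x
    psi = np.arctan2(u_z, -u_y) + 0 * x
    xi = dist_c - rc  # positive = away from the arc center
    rho = np.sqrt(xi**2 + (x - cx) ** 2)
    phi = np.arctan2((x - cx) + 0 * xi, xi)  # 0 = away from the arc center
    s = np.where(np.abs(psi) <= psi_max, (psi + psi_max) * rc, np.nan)
    return rho, phi, s, 2 * psi_max * rc


def _angle_diff(phi: np.ndarray, deg: float) -> np.ndarray:
    d = phi - np.deg2rad(deg)
    return np.abs((d + np.pi) % (2 * np.pi) - np.pi)


def generate_phantom(spec: PhantomSpec) -> tuple[GrayscaleVolume, PhantomGroundTruth]:
    """Rasterize the phantom and return the volume plus ground truth."""
    rho, phi, s, length = _local_frame(spec)
    in_span = np.isfinite(s)
    r_in = spec.lumen_radius
    r_out = r_in + spec.wall_thickness

    lumen = in_span & (rho <= r_in)
    wall = in_span & (rho > r_in) & (rho <= r_out)
    for gap in spec.branch_gaps:
        sel = (
            wall
            & (np.abs(np.where(in_span, s, -np.inf) - gap.axial_center_mm) <= gap.axial_extent_mm / 2)
            & (_angle_diff(phi, gap.angle_deg) <= np.deg2rad(gap.angular_span_deg) / 2)
        )
        wall &= ~sel

    atten = np.full(spec.shape, spec.lumen_attenuation, dtype=np.float64)
    atten[wall] = spec.wall_attenuation

    plaque = np.zeros(spec.shape, dtype=bool)
    analytic_plaque = 0.0
    arc = spec.centerline == "arc"
    for p in spec.plaques:
        s0 = p.axial_center_mm - p.axial_span_mm / 2
        s1 = p.axial_center_mm + p.axial_span_mm / 2
        if s0 < 0 or s1 > length:
            raise ValueError("plaque axial span exceeds the tube length")
        proj = rho * np.cos(phi - np.deg2rad(p.angle_deg))
        region = lumen & (proj >= r_in - p.depth_mm)
        region &= (np.where(in_span, s, -np.inf) >= s0) & (np.where(in_span, s, np.inf) <= s1)
        plaque |= region
        atten[region] = p.attenuation
        if p.core_attenuation is not None:
            dist_in = ndimage.distance_transform_edt(region)
            core = dist_in > p.core_margin_voxels
            atten[core] = p.core_attenuation
        area, centroid = _segment_geometry(r_in, p.depth_mm)
        if arc:
            dpsi = p.axial_span_mm / spec.arc_radius
            analytic_plaque += dpsi * area * (
                spec.arc_radius + centroid * np.cos(np.deg2rad(p.angle_deg))
            )
        else:
            analytic_plaque += area * p.axial_span_mm

    data = atten
    if spec.blur_sigma > 0:
        data = ndimage.gaussian_filter(data, spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    vs = spec.voxel_size
    lesion = plaque & morph.ball_dilate(wall, 1)
    truth = PhantomGroundTruth(
        wall=BinaryMask(wall, vs, "wall"),
        lumen=BinaryMask(lumen, vs, "lumen"),
        plaque=BinaryMask(plaque, vs, "plaque"),
        lesion=BinaryMask(lesion, vs, "lesion"),
        analytic_lumen_volume=np.pi * r_in**2 * length,
        analytic_plaque_volume=analytic_plaque,
        analytic_wall_thickness=spec.wall_thickness,
    )
    return GrayscaleVolume(data, vs), truth


def phantom_contours(
    spec: PhantomSpec, n_contours: int = 10, slack_voxels: float = 0.75, n_vertices: int = 48
) -> ContourSet:
    """Outer-wall contours as a manual operator would draw them.

    Circles of radius ``r_out + slack`` around the centerline on
    ``n_contours`` evenly spaced slices inside the tube span (tight to
    the outer wall, as in manual contouring).  For arc centerlines the
    radius is inflated by the local tangent tilt so the tilted
    cross-section stays inside.
    """
    nz, ny, nx = spec.shape
    vs = spec.voxel_size
    cy, cx = (c / vs for c in _tube_center(spec))  # voxel units
    z_lo = spec.axial_margin
    z_hi = nz * vs - spec.axial_margin
    # straight tubes are contoured over the whole span; for arcs stay a few
    # voxels inside so the tilted end cross-sections are whole
    inset = 0.0 if spec.centerline == "straight" else 3 * vs
    zs = np.linspace(z_lo + inset, z_hi - inset, n_contours)
    r_out = spec.lumen_radius + spec.wall_thickness

    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    contours = []
    for z in zs:
        if spec.centerline == "straight":
            idx = int(np.ceil(z / vs)) if z == zs[0] else int(np.floor(z / vs))
            center_y, radius = cy, r_out / vs + slack_voxels
        else:
            idx = int(round(z / vs))
            rc = spec.arc_radius
            z_mid = nz * vs / 2
            sin_psi = (idx * vs - z_mid) / rc
            cos_psi = np.sqrt(1 - sin_psi**2)
            center_y = (cy * vs + rc - rc * cos_psi) / vs
            radius = (r_out / cos_psi) / vs + slack_voxels
        verts = np.column_stack(
            [center_y + radius * np.cos(theta), cx + radius * np.sin(theta)]
        )
        contours.append((idx, verts))
    return ContourSet(contours, units="voxel")


def _base_spec(**kw) -> PhantomSpec:
    plaque = PlaqueSpec(angle_deg=0.0, axial_center_mm=0.52, axial_span_mm=0.5, depth_mm=0.083)
    return PhantomSpec(plaques=[plaque], **kw)


#: Named fixture levels exercising specific workflow mechanisms.
SUITE_LEVELS = ("clean", "blurred", "noisy", "branch", "confounded")


def phantom_suite(
    level: str, seed: int = 11
) -> list[tuple[PhantomSpec, GrayscaleVolume, PhantomGroundTruth]]:
    """Fixed phantom fixtures per difficulty level.

    clean      -- straight tube, one plaque, no blur/noise
    blurred    -- + partial-volume blur (sigma = 0.8 voxel)
    noisy      -- + additive noise, sd = 5% of wall attenuation
    branch     -- arc centerline with a 60-degree wall gap (branch ostium)
    confounded -- plaque with a heavily stained core above the wall
                  threshold, leaving a lumen-draft void
    """
    if level == "clean":
        specs = [_base_spec(seed=seed)]
    elif level == "blurred":
        specs = [_base_spec(blur_sigma=0.8, seed=seed)]
    elif level == "noisy":
        specs = [_base_spec(blur_sigma=0.8, noise_sd=0.4, seed=seed)]
    elif level == "branch":
        base = _base_spec(centerline="arc", arc_radius=2.0, blur_sigma=0.8, noise_sd=0.4, seed=seed)
        specs = [
            replace(
                base,
                branch_gaps=[BranchGap(axial_center_mm=0.3, angular_span_deg=60.0, angle_deg=180.0)],
            )
        ]
    elif level == "confounded":
        plaque = PlaqueSpec(
            angle_deg=0.0,
            axial_center_mm=0.52,
            axial_span_mm=0.5,
            depth_mm=0.073,
            attenuation=3.5,
            core_attenuation=6.5,
            core_margin_voxels=2.0,
        )
        specs = [PhantomSpec(plaques=[plaque], seed=seed)]
    else:
        raise ValueError(f"unknown phantom level {level!r}; expected one of {SUITE_LEVELS}")
    return [(sp, *generate_phantom(sp)) for sp in specs]
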