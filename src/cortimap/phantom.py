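"""Synthetic CT phantoms of a tibia-like long bone with known cortical thickness.

The phantom is a tube along the canonical +z axis: an outer surface of radius
``R(h)`` (h = height fraction in [0, 1], 0 at the distal/talar end) and an
inner endosteal surface at ``R(h) - T(h, theta)``, where the thickness field
``T`` may vary with height and with the sector angle ``theta`` (0 at anterior
+y, increasing toward +x).  Densities are piecewise constant (background /
cortex / trabecular, in HU), blurred by an isotropic Gaussian point-spread
function and overlaid with seeded Gaussian noise — the constant-density image
model the profile fit assumes.  Partial volume is approximated by 3x
supersampling before the blur.

Because the geometry is analytic, every extracted surface point has an exact
ground-truth thickness (``PhantomTruth.thickness_at``), which is the oracle
for the whole downstream pipeline.  Cohorts of per-subject regional
standardized thickness are drawn from per-group normal distributions
parameterized like the packaged reference tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging_io import HEIGHTS, SECTORS, CTVolume, LandmarkSet
from . import stats as _stats

# height bands (fractions of tibial length): diaphysis is 30-70%
DIAPHYSIS = (0.30, 0.70)
HEIGHT_BANDS = {"distal": (0.30, 0.43), "central": (0.43, 0.57), "proximal": (0.57, 0.70)}


def constant_radius(radius: float) -> Callable:
    return lambda h: np.full_like(np.asarray(h, dtype=float), radius)


def constant_thickness(t: float) -> Callable:
    return lambda h, theta: np.full(np.broadcast(np.asarray(h), np.asarray(theta)).shape, float(t))


def sector_thickness_field(by_sector: dict[str, float], side: str = "right",
                           blend_deg: float = 0.0) -> Callable:
    """Piecewise-constant wall thickness per 90-degree sector.

    ``by_sector`` maps 'medial'/'anterior'/'lateral'/'posterior' to mm.
    theta = 0 is anterior; +x (theta = +90 deg) is lateral on a right tibia
    and medial on a left one.  ``blend_deg`` > 0 linearly blends across
    sector boundaries over that angular width (avoids step discontinuities).
    """
    plus_x, minus_x = ("lateral", "medial") if side == "right" else ("medial", "lateral")
    order = ["anterior", plus_x, "posterior", minus_x]  # centers 0, 90, 180, 270 deg
    vals = np.array([by_sector[s] for s in order], dtype=float)

    def field(h, theta):
        theta = np.asarray(theta, dtype=float)
        deg = np.degrees(theta) % 360.0
        if blend_deg <= 0:
            idx = (np.floor((deg + 45.0) / 90.0).astype(int)) % 4
            out = vals[idx]
        else:
            # piecewise-linear interpolation between sector centers
            centers = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
            v = np.append(vals, vals[0])
            out = np.interp(deg, centers, v)
        return np.broadcast_to(out, np.broadcast(np.asarray(h), theta).shape).copy()

    return field


def sinusoidal_thickness_field(t_mean: float = 5.5, t_amp: float = 2.5,
                               phase: float = 0.0) -> Callable:
    """Smooth sector-dependent wall: t_mean + t_amp * sin(theta + phase)."""

    def field(h, theta):
        h = np.asarray(h, dtype=float)
        theta = np.asarray(theta, dtype=float)
        return t_mean + t_amp * np.sin(theta + phase) + 0.0 * h

    return field


def rounded_triangle_radius(base_radius: float, amplitude: float = 0.15) -> Callable:
    """Tibia-like rounded-triangle outer contour (radius modulated by cos 3theta).

    Returns a function of (h, theta); use with ``outer_radius_profile`` given
    as a callable of theta as well (see PhantomSpec.outer_radius_2d).
    """

    def radius(h, theta):
        theta = np.asarray(theta, dtype=float)
        return base_radius * (1.0 + amplitude * np.cos(3.0 * theta))

    return radius


@dataclass
class PhantomSpec:
    """Full description of a synthetic bone CT acquisition.

    Defaults follow the clinical acquisition the pipeline targets: in-plane
    pixels ~0.7 mm with 1.0 mm slice interval, cortex ~1500 HU over a 40 HU
    background and 150 HU trabecular interior, scanner blur sigma 0.6 mm.
    """

    bone_length: float = 360.0
    outer_radius_profile: Callable = field(default_factory=lambda: constant_radius(11.0))
    thickness_field: Callable = field(default_factory=sinusoidal_thickness_field)
    hu_background: float = 40.0
    hu_cortex: float = 1500.0
    hu_trabecular: float = 150.0
    psf_sigma: float = 0.6
    noise_sd: float = 20.0
    voxel_spacing: tuple[float, float, float] = (0.7, 0.7, 1.0)
    pose: np.ndarray | None = None  # 4x4 rigid transform of the canonical bone
    side: str = "right"
    seed: int = 0
    margin_mm: float = 6.0
    supersample: int = 3
    outer_radius_2d: Callable | None = None  # optional (h, theta) -> mm override
    extent_mm: tuple[float, float, float] | None = None  # fixed volume extent

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if not (self.hu_cortex > self.hu_trabecular and self.hu_cortex > self.hu_background):
            raise ValueError("hu_cortex must exceed hu_trabecular and hu_background")
        if self.bone_length <= 0:
            raise ValueError("bone_length must be positive")
        if self.pose is None:
            self.pose = np.eye(4)
        else:
            self.pose = np.asarray(self.pose, dtype=float)
            R = self.pose[:3, :3]
            if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
                raise ValueError("pose must be rigid (orthonormal rotation block)")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        # thickness/radius sanity on a grid
        h = np.linspace(0.0, 1.0, 41)
        th = np.linspace(0.0, 2 * np.pi, 73)
        H, TH = np.meshgrid(h, th, indexing="ij")
        R = self.outer_radius(H, TH)
        T = np.asarray(self.thickness_field(H, TH), dtype=float)
        if not np.all(T > 0):
            raise ValueError("thickness_field must be > 0 everywhere")
        if not np.all(T < R):
            raise ValueError("thickness_field must be < outer radius everywhere")

    def outer_radius(self, h, theta):
        if self.outer_radius_2d is not None:
            return np.asarray(self.outer_radius_2d(h, theta), dtype=float)
        r = np.asarray(self.outer_radius_profile(np.asarray(h, dtype=float)), dtype=float)
        return np.broadcast_to(r, np.broadcast(np.asarray(h), np.asarray(theta)).shape).copy()


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a phantom volume."""

    spec: PhantomSpec
    surface_points: np.ndarray        # (N, 3) world mm on the outer surface
    thickness: np.ndarray             # (N,) mm, exact
    region: list[str]                 # per-point region label or 'outside'
    landmarks: LandmarkSet
    tibial_length: float
    base_z: float                     # canonical world z of the distal bone end

    def to_canonical(self, points: np.ndarray) -> np.ndarray:
        """World points -> canonical (unposed) bone coordinates."""
        pose = self.spec.pose
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - pose[:3, 3]) @ pose[:3, :3]

    def h_theta(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = self.to_canonical(points)
        h = (c[:, 2] - self.base_z) / self.spec.bone_length
        theta = np.arctan2(c[:, 0], c[:, 1])
        return h, theta

    def thickness_at(self, points: np.ndarray) -> np.ndarray:
        """Exact cortical thickness of the analytic field at surface points."""
        h, theta = self.h_theta(points)
        return np.asarray(self.spec.thickness_field(np.clip(h, 0.0, 1.0), theta),
                          dtype=float)

    def region_at(self, points: np.ndarray) -> list[str]:
        h, theta = self.h_theta(points)
        return [_region_label(hi, ti, self.spec.side) for hi, ti in zip(h, theta)]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.surface_points[:, 0],
            "y": self.surface_points[:, 1],
            "z": self.surface_points[:, 2],
            "thickness": self.thickness,
            "region": self.region,
        })


def _region_label(h: float, theta: float, side: str) -> str:
    band = None
    if HEIGHT_BANDS["distal"][0] <= h < HEIGHT_BANDS["distal"][1]:
        band = "distal"
    elif HEIGHT_BANDS["central"][0] <= h < HEIGHT_BANDS["central"][1]:
        band = "central"
    elif HEIGHT_BANDS["proximal"][0] <= h <= HEIGHT_BANDS["proximal"][1]:
        band = "proximal"
    if band is None:
        return "outside"
    deg = np.degrees(theta) % 360.0
    idx = int(np.floor((deg + 45.0) / 90.0)) % 4
    plus_x, minus_x = ("lateral", "medial") if side == "right" else ("medial", "lateral")
    sector = ["anterior", plus_x, "posterior", minus_x][idx]
    return f"{band}-{sector}"


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Voxelize, blur and noise a phantom; return the volume and its truth.

    The canonical bone (distal end at z = margin, axis on the volume's XY
    center) is mapped through ``spec.pose``; the volume grid is sized to cover
    the posed bone plus ``margin_mm`` unless ``extent_mm`` pins the extent, in
    which case a bone leaving the grid is an error naming the dimension.
    """
    sx, sy, sz = spec.voxel_spacing
    L = spec.bone_length
    hh = np.linspace(0, 1, 101)
    th = np.linspace(0, 2 * np.pi, 73)
    rmax = float(np.max(spec.outer_radius(*np.meshgrid(hh, th, indexing="ij"))))

    # canonical bone: distal end at z=0, axis through (0,0)
    base = np.array([0.0, 0.0, 0.0])
    axis_samples = np.linspace(0.0, L, 37)
    ring = np.stack([np.sin(th), np.cos(th)], axis=1)  # (x, y) unit ring
    boundary = []
    for z in axis_samples:
        h = z / L
        r = np.asarray(spec.outer_radius(np.full_like(th, h), th))
        boundary.append(np.column_stack([r * ring[:, 0], r * ring[:, 1],
                                         np.full_like(th, z)]))
    boundary = np.concatenate(boundary, axis=0)
    posed = boundary @ spec.pose[:3, :3].T + spec.pose[:3, 3]

    m = spec.margin_mm
    lo = posed.min(axis=0) - m
    hi = posed.max(axis=0) + m
    if spec.extent_mm is not None:
        ext = np.asarray(spec.extent_mm, dtype=float)
        need = hi - lo
        for d, nm in enumerate("xyz"):
            if need[d] > ext[d]:
                raise ValueError(
                    f"bone exceeds the fixed volume extent along {nm}: "
                    f"needs {need[d]:.1f} mm, extent {ext[d]:.1f} mm")
        hi = lo + ext
    origin = lo
    shape = np.maximum(2, np.ceil((hi - lo) / np.array([sx, sy, sz])).astype(int))
    nx, ny, nz = (int(v) for v in shape)

    ss = int(spec.supersample)
    inv_R = spec.pose[:3, :3].T
    inv_t = -inv_R @ spec.pose[:3, 3]

    # fine in-plane grid (world x, y at supersampled voxel centers)
    def fine_axis(n, s, o):
        return o + (np.arange(n * ss) + 0.5) * (s / ss)

    fx = fine_axis(nx, sx, origin[0])
    fy = fine_axis(ny, sy, origin[1])
    fz = fine_axis(nz, sz, origin[2])
    FX, FY = np.meshgrid(fx, fy, indexing="ij")

    identity_pose = np.allclose(spec.pose, np.eye(4))
    vol = np.empty((nx, ny, nz), dtype=np.float32)
    slab = np.empty((nx * ss, ny * ss, ss), dtype=np.float64)

    def classify(cx, cy, cz):
        """HU at canonical coordinates (arrays of equal shape)."""
        h = cz / L
        r = np.hypot(cx, cy)
        theta = np.arctan2(cx, cy)
        inside_axial = (h >= 0.0) & (h <= 1.0)
        hc = np.clip(h, 0.0, 1.0)
        R = spec.outer_radius(hc, theta)
        T = np.asarray(spec.thickness_field(hc, theta), dtype=float)
        out = np.full(r.shape, spec.hu_background, dtype=float)
        in_bone = inside_axial & (r <= R)
        out[in_bone & (r <= R - T)] = spec.hu_trabecular
        out[in_bone & (r > R - T)] = spec.hu_cortex
        return out

    for k in range(nz):
        for j in range(ss):
            zw = fz[k * ss + j]
            if identity_pose:
                cx, cy = FX, FY
                cz = np.full_like(FX, zw)
            else:
                w = np.stack([FX, FY, np.full_like(FX, zw)], axis=-1)
                c = w @ inv_R.T + inv_t
                cx, cy, cz = c[..., 0], c[..., 1], c[..., 2]
            slab[:, :, j] = classify(cx, cy, cz)
        coarse = slab.reshape(nx, ss, ny, ss, ss).mean(axis=(1, 3, 4))
        vol[:, :, k] = coarse

    if spec.psf_sigma > 0:
        vol = gaussian_filter(vol.astype(np.float64),
                              sigma=[spec.psf_sigma / sx, spec.psf_sigma / sy,
                                     spec.psf_sigma / sz]).astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)

    # CTVolume's origin is the world position of the first voxel *center*
    volume = CTVolume(scalars=vol, spacing=spec.voxel_spacing,
                      origin=tuple(origin + 0.5 * np.array([sx, sy, sz])))

    truth = _build_truth(spec)
    return volume, truth


def _build_truth(spec: PhantomSpec) -> PhantomTruth:
    L = spec.bone_length
    hs = np.linspace(0.02, 0.98, max(int(L / 4.0), 25))
    th = np.linspace(0.0, 2 * np.pi, 73)[:-1]
    H, TH = np.meshgrid(hs, th, indexing="ij")
    R = spec.outer_radius(H, TH)
    pts = np.column_stack([
        (R * np.sin(TH)).ravel(),
        (R * np.cos(TH)).ravel(),
        (H * L).ravel(),
    ])
    thick = np.asarray(spec.thickness_field(H, TH), dtype=float).ravel()
    world = pts @ spec.pose[:3, :3].T + spec.pose[:3, 3]

    def posed(p):
        return spec.pose[:3, :3] @ np.asarray(p, dtype=float) + spec.pose[:3, 3]

    # PCL attachment (posterior) and tuberosity medial edge (anterior) span the
    # anteroposterior width of the proximal tibia (~58 mm), giving the y-axis a
    # baseline long enough that millimetre landmark error tilts it < 2 degrees
    med_x = -8.0 if spec.side == "right" else 8.0
    landmarks = LandmarkSet(
        pcl_attachment=posed([0.0, -28.0, 0.92 * L]),
        tuberosity_medial_edge=posed([0.0, 30.0, 0.92 * L]),
        eminence_midpoint=posed([0.0, 0.0, L]),
        talar_dome_medial=posed([med_x, 0.0, 0.0]),
        talar_dome_lateral=posed([-med_x, 0.0, 0.0]),
        side=spec.side,
    )
    regions = [_region_label(h, t, spec.side) for h, t in zip(H.ravel(), TH.ravel())]
    return PhantomTruth(spec=spec, surface_points=world, thickness=thick,
                        region=regions, landmarks=landmarks, tibial_length=L,
                        base_z=0.0)


# ---------------------------------------------------------------------------
# Synthetic cohorts of regional standardized thickness
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Normal-model cohort: per group x region mean/SD of standardized thickness.

    ``table`` columns: group, height, sector, n, mean, sd — values in the
    conventional x10^-3 standardized units.  ``tibial_length`` is the (mean,
    sd) mm of the per-subject tibial length draw.
    """

    table: pd.DataFrame
    tibial_length: tuple[float, float] = (363.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        req = {"group", "height", "sector", "n", "mean", "sd"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if not (self.table.sd > 0).all():
            bad = self.table[~(self.table.sd > 0)].iloc[0]
            raise ValueError(
                f"all SDs must be > 0; {bad.group} {bad.height}-{bad.sector} has sd {bad.sd}")
        if not (self.table.n >= 2).all():
            raise ValueError("all group sizes must be >= 2")

    @classmethod
    def from_reference(cls, seed: int = 0, n_override: int | None = None) -> "CohortSpec":
        """Spec calibrated from the packaged standardized reference table.

        95% CIs are inverted to SDs with the t-based rule
        sd = halfwidth * sqrt(n) / t_{0.975, n-1}.
        """
        ref = _stats.load_reference_table("standardized")
        ref = ref[ref.height != "total"].copy()
        ref["sd"] = [
            _stats.ci_to_sd(0.5 * (r.ci_high - r.ci_low), int(r.n))
            for r in ref.itertuples()
        ]
        if n_override is not None:
            ref["n"] = int(n_override)
        return cls(table=ref[["group", "height", "sector", "n", "mean", "sd"]],
                   seed=seed)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-subject long-format cohort table from a CohortSpec.

    Each subject's 12 regional values are independent normal draws from the
    group's (mean, sd); deterministic under the spec seed.  Columns: subject,
    group, height, sector, value (x10^-3 standardized), tibial_length_mm.
    """
    rng = np.random.default_rng(spec.seed)
    parts = []
    for group, gtab in spec.table.groupby("group", sort=False):
        n = int(gtab.n.iloc[0])
        lengths = rng.normal(spec.tibial_length[0], spec.tibial_length[1], size=n)
        k = len(gtab)
        values = np.column_stack([rng.normal(r.mean, r.sd, size=n)
                                  for r in gtab.itertuples()])  # (n, k)
        subjects = np.array([f"{group}_{i:04d}" for i in range(n)])
        parts.append(pd.DataFrame({
            "subject": np.repeat(subjects, k),
            "group": group,
            "height": np.tile(gtab.height.to_numpy(), n),
            "sector": np.tile(gtab.sector.to_numpy(), n),
            "value": values.ravel(),
            "tibial_length_mm": np.repeat(lengths, k),
        }))
    return pd.concat(parts, ignore_index=True)
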