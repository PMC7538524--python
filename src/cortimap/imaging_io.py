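"""I/O layer: CT volumes, landmark sets, surfaces with thickness maps, tables, config.

Everything downstream of the readers works in physical millimetres in patient
space; grid indices never leave this module.  The canonical volume format is
NIfTI (via nibabel); a DICOM-series importer (via pydicom) is provided for
clinical data.  Surfaces travel as ASCII PLY with a per-vertex ``thickness``
scalar, landmarks as JSON, regional tables as CSV, run configuration as YAML.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
import yaml

HEIGHTS = ("proximal", "central", "distal")
SECTORS = ("medial", "anterior", "lateral", "posterior")
#: the 12 diaphyseal region labels, height-major
REGIONS = tuple(f"{h}-{s}" for h in HEIGHTS for s in SECTORS)

LANDMARK_NAMES = (
    "pcl_attachment",
    "tuberosity_medial_edge",
    "eminence_midpoint",
    "talar_dome_medial",
    "talar_dome_lateral",
)


class VolumeFormatError(ValueError):
    """Raised for unrecognized or unsupported volume geometry/formats."""


# ---------------------------------------------------------------------------
# CT volume
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A 3-D scalar field in Hounsfield units on an anisotropic grid.

    ``scalars`` is indexed ``[i, j, k]``; the world position of a (fractional)
    index is ``origin + direction @ (index * spacing)``.  ``direction`` must be
    a proper rotation (orthonormal, det +1), i.e. axes may be permuted/rotated
    but not sheared or mirrored.
    """

    scalars: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.scalars = np.asarray(self.scalars)
        if self.scalars.ndim != 3:
            raise VolumeFormatError("volume must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"voxel spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3, 3):
            raise VolumeFormatError("direction must be 3x3")
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-5):
            raise VolumeFormatError("non-orthogonal volume axes are not supported")
        if np.linalg.det(self.direction) < 0:
            raise VolumeFormatError("volume axis orientation must be a proper rotation (det +1)")

    # -- geometry -----------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + (idx * self.spacing) @ self.direction.T

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return ((pts - np.asarray(self.origin)) @ self.direction) / np.asarray(self.spacing)

    def sample(self, pts: np.ndarray, order: int = 1, cval: float | None = None) -> np.ndarray:
        """Interpolate HU at world points (trilinear by default)."""
        from scipy.ndimage import map_coordinates

        idx = self.world_to_index(pts)
        kwargs = {"order": order}
        if cval is None:
            kwargs.update(mode="nearest")
        else:
            kwargs.update(mode="constant", cval=cval)
        return map_coordinates(self.scalars.astype(float), idx.T, **kwargs)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(pts)
        hi = np.asarray(self.scalars.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=1)


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from NIfTI (``.nii``/``.nii.gz``) or a DICOM series dir."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        img = nib.load(str(path))
        aff = np.asarray(img.affine, dtype=float)
        lin = aff[:3, :3]
        spacing = np.linalg.norm(lin, axis=0)
        if np.any(spacing <= 0):
            raise VolumeFormatError(f"degenerate voxel spacing in {path}")
        direction = lin / spacing
        return CTVolume(
            scalars=np.asanyarray(img.dataobj).astype(np.float32),
            spacing=tuple(spacing),
            origin=tuple(aff[:3, 3]),
            direction=direction,
        )
    raise VolumeFormatError(f"unrecognized volume format: {path}")


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    path = Path(path)
    img = nib.Nifti1Image(volume.scalars.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def _read_dicom_series(directory: Path) -> CTVolume:
    """Assemble a CTVolume from a directory of single-frame DICOM slices."""
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        raise VolumeFormatError(f"no DICOM slices in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    row_dir = np.asarray(slices[0].ImageOrientationPatient[:3], dtype=float)
    col_dir = np.asarray(slices[0].ImageOrientationPatient[3:], dtype=float)
    normal = np.cross(row_dir, col_dir)
    positions = np.array([s.ImagePositionPatient for s in slices], dtype=float)
    if len(slices) > 1:
        dz = np.diff(positions @ normal)
        if np.ptp(dz) > 1e-3:
            raise VolumeFormatError("non-uniform DICOM slice spacing")
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))
    ps = [float(v) for v in slices[0].PixelSpacing]  # (row spacing, col spacing) mm
    data = np.stack(
        [s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
         + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices],
        axis=-1,
    )
    # pixel_array is [row, col]; the column index advances along row_dir.
    # Transpose to [col, row, slice] so grid axes follow (row_dir, col_dir, normal).
    data = np.transpose(data, (1, 0, 2))
    direction = np.column_stack([row_dir, col_dir, normal])
    return CTVolume(
        scalars=data.astype(np.float32),
        spacing=(ps[1], ps[0], abs(slice_spacing)),
        origin=tuple(positions[0]),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Anatomical landmarks for frame construction and tibial length.

    Points are 3-D world-mm.  ``side`` ('left'/'right') is mandatory: the
    medial/lateral naming of the +x/-x sectors depends on it.
    ``circle_fit_heights`` are the two diaphyseal height fractions at which
    cross-section circles are fit for the temporal long axis.
    """

    pcl_attachment: np.ndarray
    tuberosity_medial_edge: np.ndarray
    eminence_midpoint: np.ndarray
    talar_dome_medial: np.ndarray
    talar_dome_lateral: np.ndarray
    side: str
    circle_fit_heights: tuple[float, float] = (0.30, 0.70)

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            setattr(self, name, p)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        h1, h2 = (float(h) for h in self.circle_fit_heights)
        if h1 == h2 or not (0.25 < h1 < 0.75 and 0.25 < h2 < 0.75):
            raise ValueError(
                f"circle_fit_heights must be distinct fractions in (0.25, 0.75), got {self.circle_fit_heights}"
            )
        self.circle_fit_heights = (h1, h2)
        dome_z = max(self.talar_dome_medial[2], self.talar_dome_lateral[2])
        if self.eminence_midpoint[2] <= dome_z:
            raise ValueError(
                "eminence_midpoint must lie superior (larger z) to the talar dome points"
            )

    @property
    def talar_dome_midpoint(self) -> np.ndarray:
        return 0.5 * (self.talar_dome_medial + self.talar_dome_lateral)

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        """Landmarks under a rigid 4x4 transform."""
        m = np.asarray(matrix, dtype=float)

        def t(p):
            return m[:3, :3] @ p + m[:3, 3]

        return LandmarkSet(
            pcl_attachment=t(self.pcl_attachment),
            tuberosity_medial_edge=t(self.tuberosity_medial_edge),
            eminence_midpoint=t(self.eminence_midpoint),
            talar_dome_medial=t(self.talar_dome_medial),
            talar_dome_lateral=t(self.talar_dome_lateral),
            side=self.side,
            circle_fit_heights=self.circle_fit_heights,
        )


def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    with open(path) as fh:
        data = json.load(fh)
    for name in LANDMARK_NAMES:
        if name not in data:
            raise ValueError(f"landmark file {path} is missing point {name!r}")
    if "side" not in data:
        raise ValueError(f"landmark file {path} is missing mandatory field 'side'")
    return LandmarkSet(
        **{name: np.asarray(data[name], dtype=float) for name in LANDMARK_NAMES},
        side=data["side"],
        circle_fit_heights=tuple(data.get("circle_fit_heights", (0.30, 0.70))),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    data = {name: list(map(float, getattr(landmarks, name))) for name in LANDMARK_NAMES}
    data["side"] = landmarks.side
    data["circle_fit_heights"] = list(landmarks.circle_fit_heights)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


# ---------------------------------------------------------------------------
# Surfaces + thickness maps (ASCII PLY with per-vertex scalar)
# ---------------------------------------------------------------------------

def write_thickness_map(surface, thickness: np.ndarray, path: str | os.PathLike,
                        valid: np.ndarray | None = None) -> None:
    """Write a surface plus a per-vertex ``thickness`` scalar as ASCII PLY.

    ``surface`` needs ``vertices`` (N,3) and ``faces`` (M,3) attributes (a
    BoneSurface or a trimesh).  ``thickness`` must have one value per vertex.
    """
    vertices = np.asarray(surface.vertices, dtype=float)
    faces = np.asarray(surface.faces, dtype=int)
    thickness = np.asarray(thickness, dtype=float)
    if thickness.shape[0] != vertices.shape[0]:
        raise ValueError(
            f"thickness length {thickness.shape[0]} != vertex count {vertices.shape[0]}"
        )
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.vertex_attributes["thickness"] = thickness.astype(np.float32)
    if valid is not None:
        mesh.vertex_attributes["valid"] = np.asarray(valid).astype(np.uint8)
    mesh.export(str(path), encoding="ascii")


def read_thickness_map(path: str | os.PathLike):
    """Read an ASCII PLY written by :func:`write_thickness_map`.

    Returns ``(mesh, thickness, valid)``; ``valid`` is None when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh not found: {path}")
    mesh = trimesh.load(str(path), process=False)
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
    thickness = raw.get("thickness")
    if thickness is not None:
        thickness = np.asarray(thickness, dtype=float).reshape(-1)
    valid = raw.get("valid")
    if valid is not None:
        valid = np.asarray(valid).reshape(-1).astype(bool)
    return mesh, thickness, valid


# ---------------------------------------------------------------------------
# Regional tables
# ---------------------------------------------------------------------------

def write_regional_table(summary, path: str | os.PathLike) -> None:
    """Write a RegionalSummary as CSV (one row per region).

    Columns: region, n_points, actual_mm, standardized (dimensionless) and
    standardized_e3 (the conventional x10^-3 display scale).  Empty regions
    keep their row with n_points 0 and missing-value markers.
    """
    df = summary.table.copy()
    df.to_csv(path, index=False)


def read_regional_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"regional table not found: {path}")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path: str | os.PathLike) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
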