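"""Anatomical tibial coordinate system from circle fits and landmarks.

The temporal long axis connects the centers of least-squares circles fit to
the outer diaphyseal cross-sections at two height fractions.  The y-axis is
the line from the posterior-cruciate-ligament attachment to the medial edge
of the tibial tuberosity (positive anterior).  The x-axis (positive toward
the patient's right) and the true z-axis (positive superior) complete a
right-handed orthonormal triad with y preserved exactly.  The origin is where
the true-z line through the distal circle center exits the distal end of the
segmented bone (a stand-in for the distal articular surface, which is not
segmented).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .imaging_io import LandmarkSet
from .surface import BoneSurface


class FrameError(RuntimeError):
    pass


@dataclass
class CircleFit:
    center: np.ndarray  # 3-D mm (center lifted into the slab plane)
    radius: float
    rms_residual: float


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic (Kasa) least-squares circle through 2-D points.

    Returns (center (2,), radius, rms residual).  Exact for points on a
    circle; the circumscribed circle for 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("fit_circle needs >= 3 two-dimensional points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise FrameError("cannot fit a circle to (nearly) collinear points")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise FrameError("degenerate circle fit")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - radius) ** 2)))
    return np.array([cx, cy]), radius, rms


@dataclass
class TibialFrame:
    """Origin + orthonormal right-handed axes (x right, y anterior, z superior)."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns are x, y, z in world coordinates
    side: str

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-8):
            raise FrameError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise FrameError("frame must be right-handed (det +1)")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({"origin": self.origin.tolist(),
                       "axes": self.axes.tolist(), "side": self.side}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TibialFrame":
        with open(path) as fh:
            d = json.load(fh)
        return cls(origin=np.array(d["origin"]), axes=np.array(d["axes"]),
                   side=d["side"])


def _slab_circle(vertices: np.ndarray, axis: np.ndarray, anchor: np.ndarray,
                 s_target: float, slab_half: float) -> CircleFit:
    s = (vertices - anchor) @ axis
    # widen the slab if mesh decimation left it empty (coarse ring spacing)
    half = slab_half
    for _ in range(6):
        sel = np.abs(s - s_target) <= half
        if np.count_nonzero(sel) >= 8:
            break
        half *= 1.8
    if np.count_nonzero(sel) < 3:
        raise FrameError(
            f"fewer than 3 surface points in the circle-fit slab at offset {s_target:.1f} mm")
    # in-plane orthonormal basis
    u = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    plane_origin = anchor + s_target * axis
    rel = vertices[sel] - plane_origin
    pts2 = np.column_stack([rel @ u, rel @ v])
    c2, radius, rms = fit_circle(pts2)
    center = plane_origin + c2[0] * u + c2[1] * v
    return CircleFit(center=center, radius=radius, rms_residual=rms)


def build_frame(surface: BoneSurface, landmarks: LandmarkSet,
                slab_half: float = 1.5) -> TibialFrame:
    """Construct the anatomical frame from the surface and landmarks.

    Circle fits are made at the landmark set's two ``circle_fit_heights``
    (fractions of the surface extent along its principal axis).  The stated
    positive directions (x right, y anterior, z superior) and right-
    handedness define the sign conventions of the cross products.
    """
    verts = surface.vertices[~surface.is_cap]
    centroid = verts.mean(axis=0)
    # principal axis of the tube as the initial long axis
    _, _, vt = np.linalg.svd(verts - centroid, full_matrices=False)
    axis0 = vt[0]
    sup = landmarks.eminence_midpoint - landmarks.talar_dome_midpoint
    if axis0 @ sup < 0:
        axis0 = -axis0

    s = (verts - centroid) @ axis0
    s_min, s_max = float(s.min()), float(s.max())
    h_lo, h_hi = sorted(landmarks.circle_fit_heights)
    fit_lo = _slab_circle(verts, axis0, centroid, s_min + h_lo * (s_max - s_min),
                          slab_half)
    fit_hi = _slab_circle(verts, axis0, centroid, s_min + h_hi * (s_max - s_min),
                          slab_half)

    z_temp = fit_hi.center - fit_lo.center
    nz = np.linalg.norm(z_temp)
    if nz < 1e-9:
        raise FrameError("coincident circle centers: temporal axis undefined")
    z_temp /= nz
    if z_temp @ sup < 0:
        z_temp = -z_temp

    y = landmarks.tuberosity_medial_edge - landmarks.pcl_attachment
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise FrameError("coincident y-axis landmarks")
    y /= ny

    angle = np.degrees(np.arccos(np.clip(abs(y @ z_temp), 0.0, 1.0)))
    if angle < 10.0:
        raise FrameError(
            f"temporal z-axis within 10 deg of the y-axis ({angle:.1f} deg apart): "
            "degenerate anatomy or bad landmarks")

    x = np.cross(y, z_temp)
    x /= np.linalg.norm(x)
    z = np.cross(x, y)  # unit by construction; superior component of z_temp kept

    axes = np.column_stack([x, y, z])
    # origin: the true-z line through the distal circle center, at the distal
    # end of the segmented bone
    all_s = surface.vertices @ z
    s_end = float(all_s.min())
    c = fit_lo.center if (fit_lo.center @ z) < (fit_hi.center @ z) else fit_hi.center
    origin = c + (s_end - c @ z) * z
    return TibialFrame(origin=origin, axes=axes, side=landmarks.side)


def to_frame(points: np.ndarray, frame: TibialFrame) -> np.ndarray:
    """Express world points in anatomical frame coordinates (rigid, isometric)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = (pts - frame.origin) @ frame.axes
    return out if np.asarray(points).ndim == 2 else out[0]


def from_frame(points: np.ndarray, frame: TibialFrame) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ frame.axes.T + frame.origin
    return out if np.asarray(points).ndim == 2 else out[0]
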