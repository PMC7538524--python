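"""Tibial length, 12-region labelling and regional thickness summaries.

Heights are fractions of the tibial length (eminence midpoint to talar-dome
midpoint) measured along the anatomical z-coordinate: distal 30-43%, central
43-57%, proximal 57-70% (half-open bands; the diaphysis is 30-70%).  Each
height band is split into four 90-degree sectors about the band's own
centroid in the xy-plane: anterior within 45 degrees of +y, posterior of -y,
and the +/-x sectors named lateral/medial according to side (right tibia:
lateral = +x).  Regional summaries report the mean actual thickness and the
standardized thickness (divided by tibial length, conventionally displayed
x10^-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cbm import ThicknessMap
from .frame import TibialFrame, to_frame
from .imaging_io import HEIGHTS, REGIONS, SECTORS, LandmarkSet
from .surface import BoneSurface

HEIGHT_BANDS = {"distal": (0.30, 0.43), "central": (0.43, 0.57),
                "proximal": (0.57, 0.70)}
OUTSIDE = "outside"


def tibial_length(landmarks: LandmarkSet) -> float:
    """Eminence midpoint to talar-dome midpoint distance (100% of length)."""
    return float(np.linalg.norm(landmarks.eminence_midpoint
                                - landmarks.talar_dome_midpoint))


def assign_height(z_fraction) -> np.ndarray:
    """Height band per z-fraction: half-open [0.30,0.43) distal, [0.43,0.57)
    central, [0.57,0.70] proximal, else 'outside'."""
    zf = np.atleast_1d(np.asarray(z_fraction, dtype=float))
    out = np.full(zf.shape, OUTSIDE, dtype=object)
    out[(zf >= 0.30) & (zf < 0.43)] = "distal"
    out[(zf >= 0.43) & (zf < 0.57)] = "central"
    out[(zf >= 0.57) & (zf <= 0.70)] = "proximal"
    return out


def assign_sector(points_xy: np.ndarray, side: str,
                  center: np.ndarray | None = None) -> np.ndarray:
    """Sector per point from the angle about ``center`` in the frame xy-plane.

    The angle is measured from +y (anterior) toward +x; sector boundaries at
    exactly 45 degrees belong to the next sector counter-clockwise (half-open,
    deterministic).  Points at the axis (radius ~ 0) cannot be classified.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))[:, :2]
    if center is not None:
        pts = pts - np.asarray(center, dtype=float)[:2]
    r = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(r < 1e-9):
        raise ValueError("point on the long axis: sector angle undefined")
    deg = np.degrees(np.arctan2(pts[:, 0], pts[:, 1])) % 360.0
    idx = np.floor(((deg + 45.0) % 360.0) / 90.0).astype(int)
    plus_x, minus_x = ("lateral", "medial") if side == "right" else ("medial", "lateral")
    names = np.array(["anterior", plus_x, "posterior", minus_x], dtype=object)
    return names[idx]


def assign_regions(surface: BoneSurface, frame: TibialFrame,
                   landmarks: LandmarkSet) -> np.ndarray:
    """Per-vertex region label ('height-sector' or 'outside').

    Sector angles are measured about each height band's own vertex centroid,
    so diaphyseal bow does not bias sector membership.
    """
    length = tibial_length(landmarks)
    if length <= 0:
        raise ValueError("tibial length is zero: landmarks degenerate")
    vf = to_frame(surface.vertices, frame)
    dome_z = to_frame(landmarks.talar_dome_midpoint, frame)[2]
    zfrac = (vf[:, 2] - dome_z) / length
    bands = assign_height(zfrac)
    labels = np.full(surface.n_vertices, OUTSIDE, dtype=object)
    for band in HEIGHTS:
        sel = (bands == band) & (~surface.is_cap)
        if not np.any(sel):
            continue
        center = vf[sel, :2].mean(axis=0)
        sectors = assign_sector(vf[sel], side=frame.side, center=center)
        labels[sel] = [f"{band}-{s}" for s in sectors]
    labels[surface.is_cap] = OUTSIDE
    return labels


@dataclass
class RegionalSummary:
    """Per-region point counts and mean actual/standardized thickness."""

    table: pd.DataFrame
    tibial_length: float

    def region(self, name: str) -> pd.Series:
        return self.table.set_index("region").loc[name]


def summarize(surface: BoneSurface, tmap: ThicknessMap, frame: TibialFrame,
              landmarks: LandmarkSet) -> RegionalSummary:
    """Mean valid-vertex thickness per region, actual and standardized.

    Empty regions keep their row with n_points 0 and NaN means (flagged, not
    fatal).  standardized = actual / tibial_length exactly, at summary level.
    """
    length = tibial_length(landmarks)
    labels = assign_regions(surface, frame, landmarks)
    rows = []
    for region in REGIONS:
        height, sector = region.split("-")
        sel = (labels == region) & tmap.valid
        n = int(np.count_nonzero(sel))
        if n:
            actual = float(np.mean(tmap.thickness[sel]))
            standardized = actual / length
        else:
            actual = float("nan")
            standardized = float("nan")
        rows.append(dict(region=region, height=height, sector=sector,
                         n_points=n, actual_mm=actual,
                         standardized=standardized,
                         standardized_e3=standardized * 1e3))
    return RegionalSummary(table=pd.DataFrame(rows), tibial_length=length)
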