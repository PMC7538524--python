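"""Model-based sub-voxel cortical thickness estimation (cortical bone mapping).

At each surface vertex, CT values are sampled along a short line perpendicular
to the cortex and fitted with a blurred three-level density model

    m(x) = y0 + (y1 - y0) * Phi((x - x0)/sigma) + (y2 - y1) * Phi((x - x1)/sigma)

where Phi is the standard normal CDF, x increases inward (0 at the vertex),
y0/y1/y2 are background, cortical and trabecular densities (HU), x0/x1 the
periosteal and endosteal edge positions (mm), sigma the imaging blur, and the
cortical thickness is t = x1 - x0.

For thin cortices the blur makes y1 and t jointly unidentifiable: the free fit
trades density against width and overestimates t.  The pipeline therefore runs
two passes: free fits everywhere, a robust global cortical density estimated
from thick-cortex fits (where the edges are separated well beyond the blur and
y1 is resolved), then density-constrained refits with y1 fixed — the
constant-density mechanism that keeps thin-cortex estimates accurate below the
voxel scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.optimize import least_squares

from .imaging_io import CTVolume
from .surface import BoneSurface

_SQRT2 = math.sqrt(2.0)


def _phi(z):
    return 0.5 * (1.0 + special.erf(z / _SQRT2))


def _pdf(z):
    return np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


@dataclass
class LineProfile:
    """HU samples along the surface normal; positions increase inward, 0 at vertex."""

    positions: np.ndarray
    values: np.ndarray
    vertex_id: int = -1
    clipped: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions/values must be equal-length 1-D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class CBMFit:
    """Fitted line-profile model at one vertex."""

    y0: float
    y1: float
    y2: float
    x0: float
    x1: float
    sigma: float
    rms_residual: float
    status: str  # 'free-fit' | 'density-constrained' | 'failed'
    vertex_id: int = -1

    @property
    def thickness(self) -> float:
        return self.x1 - self.x0

    @property
    def ok(self) -> bool:
        return self.status != "failed"


@dataclass
class ThicknessMap:
    """Per-vertex thickness with validity flags and the global density used."""

    thickness: np.ndarray
    valid: np.ndarray
    global_density: float | None = None
    fits: list | None = None

    def __len__(self) -> int:
        return len(self.thickness)

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid))


def model_profile(x, y0, y1, y2, x0, x1, sigma):
    """The blurred three-level density model evaluated at positions x."""
    x = np.asarray(x, dtype=float)
    return y0 + (y1 - y0) * _phi((x - x0) / sigma) + (y2 - y1) * _phi((x - x1) / sigma)


def sample_profile(volume: CTVolume, vertex, normal, half_length: float = 9.0,
                   step: float = 0.25, vertex_id: int = -1) -> LineProfile:
    """Trilinearly sample HU along the inward-pointing normal line.

    The outward normal defines negative positions (outside the bone); samples
    leaving the volume are clipped off with a warning, keeping the largest
    window around position 0.
    """
    vertex = np.asarray(vertex, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if not volume.contains(vertex[None, :])[0]:
        raise ValueError(f"vertex {vertex_id} lies outside the volume")
    n = int(round(half_length / step))
    positions = np.arange(-n, n + 1) * step
    points = vertex[None, :] - positions[:, None] * normal[None, :]
    inside = volume.contains(points)
    clipped = not np.all(inside)
    if clipped:
        centre = n
        lo = centre
        while lo > 0 and inside[lo - 1]:
            lo -= 1
        hi = centre
        while hi < len(positions) - 1 and inside[hi + 1]:
            hi += 1
        positions = positions[lo:hi + 1]
        points = points[lo:hi + 1]
        warnings.warn(f"profile at vertex {vertex_id} clipped to volume bounds")
    values = volume.sample(points)
    return LineProfile(positions=positions, values=values, vertex_id=vertex_id,
                       clipped=clipped)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _initial_guess(profile: LineProfile, sigma_init: float):
    x = profile.positions
    v = profile.values
    g = np.gradient(v, x)
    i0 = int(np.argmax(g))
    rest = g[i0 + 1:]
    if rest.size:
        i1 = i0 + 1 + int(np.argmin(rest))
    else:
        i1 = i0
    x0 = float(x[i0])
    x1 = float(x[i1]) if i1 > i0 else x0 + 4 * sigma_init
    y0 = float(np.mean(v[x < x0 - 1.0])) if np.any(x < x0 - 1.0) else float(v[0])
    y2 = float(np.mean(v[x > x1 + 1.0])) if np.any(x > x1 + 1.0) else float(v[-1])
    y1 = float(np.max(v))
    return y0, y1, y2, x0, max(x1 - x0, 0.2), sigma_init


def fit_profile(profile: LineProfile, density_constraint: float | None = None,
                sigma_init: float = 0.5, max_nfev: int = 200,
                x0_max_offset: float = 3.0) -> CBMFit:
    """Bounded nonlinear least-squares fit of the blurred three-level model.

    With ``density_constraint`` the cortical level y1 is fixed and only
    (y0, y2, x0, t, sigma) are estimated.  The fit is parameterized in the
    thickness t = x1 - x0 (bounded positive) so edges cannot invert.  A fit is
    'failed' when the optimizer does not converge, the recovered cortical
    level does not exceed both plateaus, or the periosteal edge is pinned at a
    bound / far from the vertex (|x0| > ``x0_max_offset``).
    """
    x = profile.positions
    v = profile.values
    span = float(x[-1] - x[0])
    if span < 1.0 or x[0] > -0.5 or x[-1] < 0.5:
        return CBMFit(0, 0, 0, 0, 0, sigma_init, float("nan"), "failed",
                      profile.vertex_id)
    y0i, y1i, y2i, x0i, ti, si = _initial_guess(profile, sigma_init)
    vmin, vmax = float(v.min()), float(v.max())
    pad = 0.25 * (vmax - vmin) + 1.0
    sigma_lo, sigma_hi = 0.05, 3.0
    x0_lo, x0_hi = float(x[0]), float(x[-1]) - 0.05
    t_lo, t_hi = 0.05, span

    fixed_y1 = density_constraint is not None
    if fixed_y1:
        y1_fixed = float(density_constraint)

        def pack(p):
            y0, y2, x0, t, s = p
            return y0, y1_fixed, y2, x0, t, s

        p0 = [y0i, y2i, x0i, ti, si]
        lb = [vmin - pad, vmin - pad, x0_lo, t_lo, sigma_lo]
        ub = [vmax + pad, vmax + pad, x0_hi, t_hi, sigma_hi]
    else:
        def pack(p):
            return tuple(p)

        p0 = [y0i, y1i, y2i, x0i, ti, si]
        lb = [vmin - pad, vmin - pad, vmin - pad, x0_lo, t_lo, sigma_lo]
        ub = [vmax + pad, vmax + pad + pad, vmax + pad, x0_hi, t_hi, sigma_hi]
    p0 = np.clip(p0, lb, ub)

    def residuals(p):
        y0, y1, y2, x0, t, s = pack(p)
        return model_profile(x, y0, y1, y2, x0, x0 + t, s) - v

    def jacobian(p):
        y0, y1, y2, x0, t, s = pack(p)
        u0 = (x - x0) / s
        u1 = (x - x0 - t) / s
        P0, P1 = _phi(u0), _phi(u1)
        f0, f1 = _pdf(u0), _pdf(u1)
        d_y0 = 1.0 - P0
        d_y1 = P0 - P1
        d_y2 = P1
        d_x1 = -(y2 - y1) * f1 / s
        d_x0 = -(y1 - y0) * f0 / s + d_x1
        d_t = d_x1
        d_s = -(y1 - y0) * f0 * u0 / s - (y2 - y1) * f1 * u1 / s
        if fixed_y1:
            cols = [d_y0, d_y2, d_x0, d_t, d_s]
        else:
            cols = [d_y0, d_y1, d_y2, d_x0, d_t, d_s]
        return np.column_stack(cols)

    try:
        res = least_squares(residuals, p0, jac=jacobian, bounds=(lb, ub),
                            max_nfev=max_nfev)
    except Exception:
        return CBMFit(y0i, y1i, y2i, x0i, x0i + ti, si, float("nan"), "failed",
                      profile.vertex_id)
    y0, y1, y2, x0, t, s = pack(res.x)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    status = "density-constrained" if fixed_y1 else "free-fit"
    eps = 1e-6
    edge_pinned = (t >= t_hi - eps) or (x0 <= x0_lo + eps) or (x0 >= x0_hi - eps)
    if (not res.success or edge_pinned or y1 <= max(y0, y2)
            or abs(x0) > x0_max_offset or t <= t_lo + eps):
        status = "failed"
    return CBMFit(float(y0), float(y1), float(y2), float(x0), float(x0 + t),
                  float(s), rms, status, profile.vertex_id)


def estimate_global_density(fits: list[CBMFit], min_fits: int = 50,
                            thickness_cutoff_sigmas: float = 3.0) -> float:
    """Robust global cortical density: median y1 over well-resolved free fits.

    Only free fits whose thickness exceeds ``thickness_cutoff_sigmas`` times
    their own fitted blur qualify (edges separated well beyond the blur leave
    the cortical plateau, making y1 identifiable).
    """
    ys = [f.y1 for f in fits
          if f.ok and f.status == "free-fit"
          and f.thickness > thickness_cutoff_sigmas * f.sigma]
    if len(ys) < min_fits:
        raise RuntimeError(
            f"only {len(ys)} free fits qualify for density estimation "
            f"(need {min_fits}); lower min_fits or the thickness cutoff")
    return float(np.median(ys))


@dataclass
class CBMParams:
    half_length: float = 9.0
    step: float = 0.25
    sigma_init: float = 0.5
    min_density_fits: int = 50
    thickness_cutoff_sigmas: float = 3.0
    x0_max_offset: float = 3.0
    keep_fits: bool = False


def map_thickness(volume: CTVolume, surface: BoneSurface,
                  params: CBMParams | None = None) -> ThicknessMap:
    """Two-pass cortical thickness map over all (non-cap) surface vertices.

    Pass 1 fits every profile freely; the global cortical density is the
    robust median over thick-cortex free fits; pass 2 refits every profile
    with y1 fixed to it.  Per-vertex failures are recorded as invalid, never
    fatal.
    """
    params = params or CBMParams()
    n = surface.n_vertices
    thickness = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    profiles: dict[int, LineProfile] = {}
    free_fits: dict[int, CBMFit] = {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            if surface.is_cap[i]:
                continue
            try:
                prof = sample_profile(volume, surface.vertices[i], surface.normals[i],
                                      half_length=params.half_length,
                                      step=params.step, vertex_id=i)
            except ValueError:
                continue
            profiles[i] = prof
            free_fits[i] = fit_profile(prof, sigma_init=params.sigma_init,
                                       x0_max_offset=params.x0_max_offset)

    density = estimate_global_density(
        list(free_fits.values()), min_fits=params.min_density_fits,
        thickness_cutoff_sigmas=params.thickness_cutoff_sigmas)

    final_fits: list[CBMFit] = []
    for i, prof in profiles.items():
        fit = fit_profile(prof, density_constraint=density,
                          sigma_init=params.sigma_init,
                          x0_max_offset=params.x0_max_offset)
        if not fit.ok and free_fits[i].ok:
            fit = free_fits[i]  # fall back to the free fit rather than drop
        if fit.ok:
            thickness[i] = fit.thickness
            valid[i] = True
        if params.keep_fits:
            final_fits.append(fit)

    return ThicknessMap(thickness=thickness, valid=valid, global_density=density,
                        fits=final_fits if params.keep_fits else None)


# ---------------------------------------------------------------------------
# Surface-domain smoothing
# ---------------------------------------------------------------------------

def smooth_map(surface: BoneSurface, tmap: ThicknessMap,
               radius: float = 3.0) -> ThicknessMap:
    """Neighbourhood smoothing of the thickness map over the surface graph.

    Uses symmetric graph-Laplacian diffusion on the mesh edge graph, which
    conserves the map total (hence the mean of a fully valid map) exactly;
    the number of diffusion steps grows with (radius / edge length)^2 to
    emulate the requested geodesic smoothing radius.  Invalid vertices are
    first imputed from their nearest valid graph neighbours; their flags stay
    invalid.  radius <= 0 is the identity.
    """
    values = tmap.thickness.copy()
    valid = tmap.valid.copy()
    if radius <= 0:
        return ThicknessMap(values, valid, tmap.global_density)

    edges = surface.mesh.edges_unique
    # cap apexes are high-degree hubs with no thickness estimate; keep them
    # out of the diffusion graph so they neither drag nor throttle the update
    cap = np.asarray(surface.is_cap)
    edges = edges[~(cap[edges[:, 0]] | cap[edges[:, 1]])]
    n = len(values)
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    d_max = max(float(deg.max()), 1.0)

    # impute invalid vertices from valid neighbours (iterative flood fill)
    filled = valid.copy()
    values[~filled] = 0.0
    for _ in range(n):
        if filled.all():
            break
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for a, b in ((edges[:, 0], edges[:, 1]), (edges[:, 1], edges[:, 0])):
            sel = filled[b]
            np.add.at(acc, a[sel], values[b[sel]])
            np.add.at(cnt, a[sel], 1.0)
        newly = (~filled) & (cnt > 0)
        if not newly.any():
            break
        values[newly] = acc[newly] / cnt[newly]
        filled |= newly

    edge_len = np.linalg.norm(surface.vertices[edges[:, 0]]
                              - surface.vertices[edges[:, 1]], axis=1)
    h = float(np.median(edge_len))
    steps = max(1, int(round((radius / max(h, 1e-6)) ** 2)))
    lam = 0.8
    for _ in range(steps):
        acc = np.zeros(n)
        np.add.at(acc, edges[:, 0], values[edges[:, 1]])
        np.add.at(acc, edges[:, 1], values[edges[:, 0]])
        values = values + lam * (acc - deg * values) / d_max

    return ThicknessMap(values, valid, tmap.global_density)


def fits_to_table(fits: list[CBMFit]):
    import pandas as pd

    return pd.DataFrame([
        dict(vertex=f.vertex_id, y0=f.y0, y1=f.y1, y2=f.y2, x0=f.x0, x1=f.x1,
             sigma=f.sigma, thickness=f.thickness, residual=f.rms_residual,
             status=f.status)
        for f in fits
    ])
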