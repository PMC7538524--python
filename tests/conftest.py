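import numpy as np
import pytest

import cortimap as cm
from cortimap.phantom import (PhantomSpec, make_phantom, constant_radius,
                              constant_thickness, sector_thickness_field,
                              sinusoidal_thickness_field)
from cortimap.surface import SliceContour, build_surface

# Table-style young-men total-diaphysis sector means (mm) used for the
# full-length reference phantom
YOUNG_MEN_SECTOR_MM = {"medial": 5.7, "lateral": 6.2, "anterior": 10.2,
                       "posterior": 6.4}


@pytest.fixture(scope="session")
def annulus_phantom():
    """Noiseless, unblurred circular annulus: outer 12 mm, wall 5 mm."""
    spec = PhantomSpec(bone_length=40.0,
                       outer_radius_profile=constant_radius(12.0),
                       thickness_field=constant_thickness(5.0),
                       psf_sigma=0.0, noise_sd=0.0, seed=0)
    volume, truth = make_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def annulus_surface(annulus_phantom):
    _, volume, _ = annulus_phantom
    return cm.extract_surface(volume, target_vertices=(300, 700))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Clinical-condition phantom: 0.7x0.7x1.0 mm voxels, PSF 0.6 mm,
    noise 20 HU, wall thickness 3-8 mm (sinusoidal by sector angle)."""
    spec = PhantomSpec(bone_length=60.0,
                       thickness_field=sinusoidal_thickness_field(5.5, 2.5),
                       psf_sigma=0.6, noise_sd=20.0, seed=3)
    volume, truth = make_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def noisy_surface(noisy_phantom):
    _, volume, _ = noisy_phantom
    return cm.extract_surface(volume, target_vertices=(800, 1500))


@pytest.fixture(scope="session")
def noisy_thickness_map(noisy_phantom, noisy_surface):
    _, volume, _ = noisy_phantom
    return cm.map_thickness(volume, noisy_surface, cm.CBMParams())


@pytest.fixture(scope="session")
def long_phantom():
    """Full-length tibia phantom (363.1 mm) with the young-men sector wall."""
    spec = PhantomSpec(bone_length=363.1,
                       thickness_field=sector_thickness_field(
                           YOUNG_MEN_SECTOR_MM, side="right", blend_deg=0.0),
                       psf_sigma=0.6, noise_sd=20.0, seed=1)
    volume, truth = make_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def long_surface(long_phantom):
    _, volume, _ = long_phantom
    return cm.extract_surface(volume)  # default 5000-9000 vertex band


@pytest.fixture(scope="session")
def long_frame(long_phantom, long_surface):
    _, _, truth = long_phantom
    return cm.build_frame(long_surface, truth.landmarks)


def make_tube_surface(radius: float = 11.0, length: float = 60.0,
                      taper: float = 0.0, n_rings: int = 31,
                      band: tuple[int, int] = (900, 1600)):
    """Analytic cylinder/cone surface, bypassing voxelization."""
    th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    contours = []
    for k, z in enumerate(np.linspace(0.0, length, n_rings)):
        r = radius - taper * z
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        contours.append(SliceContour(slice_index=k, points=pts, z=float(z)))
    return build_surface(contours, target_vertices=band)


def rigid(axis, angle_deg, translation):
    """4x4 rigid transform: rotation about a unit axis then translation."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = np.asarray(translation, dtype=float)
    return m
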