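"""Shared fixtures: phantoms at two voxel pitches, meshes, rendered frames.

Everything is generated programmatically; the expensive 0.5 mm phantom and
its curvature field are session-scoped.
"""
from __future__ import annotations

import numpy as np
import pytest
import trimesh

from condylenav import (CameraModel, PhantomSpec, Plane, make_femur_phantom,
                        refine_mask, render_arthro_frame, resect_medial,
                        segment_volume, extract_surface, vertex_curvatures)


@pytest.fixture(scope="session")
def phantom_fine():
    """Default phantom at the native 0.5 mm pitch."""
    spec = PhantomSpec()
    vol, truth = make_femur_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def fine_mesh(phantom_fine):
    _, vol, truth = phantom_fine
    mask = refine_mask(segment_volume(vol, truth.threshold), 1)
    return extract_surface(mask, smooth_sigma=1.5)


@pytest.fixture(scope="session")
def lateral_fine(phantom_fine, fine_mesh):
    """Resected lateral mesh + its (smoothed) curvature field."""
    _, _, truth = phantom_fine
    plane = Plane.from_point_normal([0.0, 0.0, 0.0], [1.0, 0.0, 0.0])
    lat = resect_medial(fine_mesh, plane, truth.lateral_marker_pt)
    curv = vertex_curvatures(lat, smooth_iters=2)
    return lat, curv


@pytest.fixture(scope="session")
def phantom_coarse():
    """Fast 1 mm phantom for pipeline-level tests."""
    spec = PhantomSpec(voxel_spacing=(1.0, 1.0, 1.0))
    vol, truth = make_femur_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def coarse_mesh(phantom_coarse):
    _, vol, truth = phantom_coarse
    mask = refine_mask(segment_volume(vol, truth.threshold), 1)
    return extract_surface(mask, smooth_sigma=1.5)


@pytest.fixture(scope="session")
def std_camera():
    """Arthroscope-like close-up of the lateral condyle's medial aspect."""
    return CameraModel.look_at(np.array([-30.0, -20.0, -30.0]),
                               np.array([15.0, -6.0, -11.0]),
                               up=(0, 0, 1), fx=250, fy=250,
                               width=256, height=256)


@pytest.fixture(scope="session")
def std_frame(fine_mesh, phantom_fine, std_camera):
    _, _, truth = phantom_fine
    frame, crease_px = render_arthro_frame(fine_mesh, std_camera, truth)
    return frame, crease_px


@pytest.fixture(scope="session")
def sphere5():
    return trimesh.creation.icosphere(subdivisions=4, radius=5.0)


@pytest.fixture(scope="session")
def unit_sphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def cylinder_tube():
    """Open cylinder r=2 with interior vertices (rings along the axis)."""
    nt, nz = 64, 21
    th = np.linspace(0, 2 * np.pi, nt, endpoint=False)
    zz = np.linspace(-5, 5, nz)
    T, Z = np.meshgrid(th, zz)
    V = np.stack([2 * np.cos(T).ravel(), 2 * np.sin(T).ravel(), Z.ravel()], axis=1)
    faces = []
    for i in range(nz - 1):
        for j in range(nt):
            a = i * nt + j
            b = i * nt + (j + 1) % nt
            c = (i + 1) * nt + j
            d = (i + 1) * nt + (j + 1) % nt
            faces += [[a, b, d], [a, d, c]]
    return trimesh.Trimesh(V, faces, process=False)
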