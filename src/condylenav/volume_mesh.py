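"""CT-style volume I/O, threshold segmentation, and marching-cubes surfacing.

The distal femur arrives as a volumetric image (NIfTI); bone is separated
from background by an intensity threshold (CT bone is naturally
high-contrast), the binary mask is cleaned up morphologically, and the
surface is reconstructed with marching cubes in millimetre coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.ndimage as ndi
import trimesh
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes
from skimage.morphology import ball

#: canonical triangulated-surface container (vertices in mm)
SurfaceMesh = trimesh.Trimesh


@dataclass
class VolumeImage:
    """Scalar 3D image with axes ordered (x, y, z), spacing/origin in mm."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive per axis")

    @property
    def shape(self):
        return self.voxels.shape

    def save_nifti(self, path: str | Path) -> None:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), affine), str(path))

    @classmethod
    def load_nifti(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        return cls(np.asarray(img.dataobj), spacing=spacing, origin=affine[:3, 3])


@dataclass
class BinaryMask:
    """Boolean 3D mask sharing the geometry of its source volume."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self):
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


def segment_volume(vol: VolumeImage, threshold: float | None = None) -> BinaryMask:
    """Threshold segmentation: mask = voxels >= threshold.

    With ``threshold=None`` an Otsu threshold on the intensity histogram is
    used (no fixed HU cutoff is assumed).
    """
    voxels = np.asarray(vol.voxels, dtype=float)
    if not np.all(np.isfinite(voxels)):
        raise ValueError("volume contains non-finite voxels")
    if threshold is None:
        threshold = float(threshold_otsu(voxels))
    return BinaryMask(voxels >= threshold, spacing=vol.spacing, origin=vol.origin)


def refine_mask(mask: BinaryMask, radius: int = 1) -> BinaryMask:
    """Morphological closing (ball structuring element) + largest component.

    Closing fills small concavities/holes left by intensity noise; keeping
    only the largest connected component isolates the femur from
    disconnected speckle.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    m = mask.voxels
    if not m.any():
        raise ValueError("empty mask")
    if radius > 0:
        selem = ball(radius)
        pad = radius + 1
        mp = np.pad(m, pad)
        mp = ndi.binary_closing(mp, structure=selem)
        m = mp[pad:-pad, pad:-pad, pad:-pad]
    labels, n = ndi.label(m)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(m, spacing=mask.spacing, origin=mask.origin)


def extract_surface(mask: BinaryMask, smooth_sigma: float = 1.0) -> SurfaceMesh:
    """Marching-cubes surface of a binary mask, in mm.

    The mask indicator is optionally Gaussian-smoothed (sigma in voxels)
    before contouring at the 0.5 iso-level; this recovers sub-voxel surface
    placement on smooth anatomy while leaving planted creases sharp at the
    scale of the structures of interest. The volume is zero-padded so solid
    masks yield watertight meshes.
    """
    m = mask.voxels
    if not (m.any() and (~m).any()):
        raise ValueError("mask must contain both foreground and background")
    f = np.pad(m.astype(np.float32), 1)
    if smooth_sigma > 0:
        f = ndi.gaussian_filter(f, smooth_sigma)
    verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=tuple(mask.spacing))
    verts = verts - mask.spacing + mask.origin  # undo the 1-voxel pad
    return trimesh.Trimesh(vertices=verts, faces=faces, process=True, validate=True)


def make_mesh(vertices: np.ndarray, faces: np.ndarray) -> SurfaceMesh:
    """Validating SurfaceMesh constructor: drops degenerate faces, checks indices."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise ValueError("face indices out of range")
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=True, validate=True)


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write PLY or STL (chosen by extension, binary little-endian)."""
    mesh.export(str(path))


def load_mesh(path: str | Path) -> SurfaceMesh:
    m = trimesh.load_mesh(str(path), process=True)
    return m
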