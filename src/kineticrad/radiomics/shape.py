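"""3D shape descriptors of the tumor mask.

Mesh-based quantities (volume, surface area, sphericity) use a marching-
cubes triangulation of the binary mask in physical (mm) coordinates;
axis lengths come from the principal-component eigenvalues of the voxel
centre coordinates, with axis length = 4 * sqrt(eigenvalue). Maximum 2D
diameters are the largest in-plane distances between surface voxels,
computed per fixed-axis plane and maximised over planes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0))


def _surface_points(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3)))
    pts = np.argwhere(mask & ~eroded)
    return pts if pts.size else np.argwhere(mask)


def _max_pairwise(points_mm: np.ndarray) -> float:
    if len(points_mm) < 2:
        return 0.0
    if len(points_mm) > 400:
        uniq = np.unique(points_mm, axis=0)
        if len(uniq) > 4:
            try:
                points_mm = uniq[ConvexHull(uniq, qhull_options="QJ").vertices]
            except Exception:  # degenerate (coplanar etc.); brute force
                points_mm = uniq
    return float(pdist(points_mm).max())


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask) > 0
    spacing = np.asarray(spacing, dtype=np.float64)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty mask")

    verts, faces = _mesh(mask, spacing)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)
    voxel_volume = n_vox * float(np.prod(spacing))

    coords = np.argwhere(mask) * spacing
    centered = coords - coords.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(centered.T @ centered / n_vox))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    surf = _surface_points(mask)
    surf_mm = surf * spacing

    def max_2d(fixed_axis: int) -> float:
        best = 0.0
        other = [a for a in range(3) if a != fixed_axis]
        for v in np.unique(surf[:, fixed_axis]):
            pts = surf_mm[surf[:, fixed_axis] == v][:, other]
            best = max(best, _max_pairwise(pts))
        return best

    sphericity = (
        (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
        if surface_area > 0
        else 0.0
    )
    return {
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
        "LeastAxisLength": least,
        "MajorAxisLength": major,
        "Maximum2DDiameterColumn": max_2d(1),  # coronal plane (y fixed)
        "Maximum2DDiameterRow": max_2d(0),  # sagittal plane (x fixed)
        "Maximum2DDiameterSlice": max_2d(2),  # axial plane (z fixed)
        "Maximum3DDiameter": _max_pairwise(surf_mm),
        "MeshVolume": mesh_volume,
        "MinorAxisLength": minor,
        "Sphericity": float(sphericity),
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "VoxelVolume": voxel_volume,
    }
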