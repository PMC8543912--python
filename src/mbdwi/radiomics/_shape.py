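"""3D shape features of a binary lesion mask: 14 features.

Surface quantities come from a marching-cubes triangulation of the mask
(computed on a zero-padded copy so boundary faces are closed); axis lengths
come from the eigenvalues of the physical-coordinate covariance of the
masked voxel centers.  2D maximum diameters are measured on voxel centers
within each slice/row/column plane.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


#: surface anti-aliasing: the padded binary mask is smoothed by this sigma
#: (voxels) before triangulation, which removes the stair-step bias of
#: marching cubes on binary data (a raw binary mesh overestimates surface
#: area by ~8-10% regardless of resolution) at <1% cost in mesh volume.
_SURFACE_SIGMA = 0.6


def _mesh(mask: np.ndarray, spacing):
    from scipy import ndimage

    padded = ndimage.gaussian_filter(np.pad(mask.astype(float), 1),
                                     _SURFACE_SIGMA)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing, dtype=float)  # undo the pad shift
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = float(np.linalg.norm(cross, axis=1).sum() / 2.0)
    vol = float(abs(np.einsum("ij,ij->", tri[:, 0],
                              np.cross(tri[:, 1], tri[:, 2])) / 6.0))
    return verts, area, vol


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def _max_2d_diameter(coords_mm: np.ndarray, idx: np.ndarray,
                     drop_axis: int) -> float:
    """Max in-plane voxel-center distance over planes fixed along one axis."""
    keep = [a for a in range(3) if a != drop_axis]
    best = 0.0
    for plane in np.unique(idx[:, drop_axis]):
        pts = coords_mm[idx[:, drop_axis] == plane][:, keep]
        best = max(best, _max_pairwise(pts))
    return best


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("shape features undefined for a single-voxel mask")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))

    verts, area, mesh_volume = _mesh(mask, spacing)
    idx = np.argwhere(mask)
    coords = idx * spacing

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]  # descending
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume,
        "Sphericity": sphericity,
        "Maximum3DDiameter": _max_pairwise(verts),
        "Maximum2DDiameterSlice": _max_2d_diameter(coords, idx, 2),
        "Maximum2DDiameterColumn": _max_2d_diameter(coords, idx, 1),
        "Maximum2DDiameterRow": _max_2d_diameter(coords, idx, 0),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
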