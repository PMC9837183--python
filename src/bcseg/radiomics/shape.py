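"""Shape (morphology) features of a 3D binary ROI: 14 descriptors.

Surface-dependent features use a triangular mesh of the mask boundary
(marching cubes at iso-level 0.5 on the zero-padded mask, in physical mm
coordinates); the mesh volume follows from the divergence theorem.  Axis
lengths derive from the eigenvalues of the (sample) covariance of the
physical voxel coordinates, as 4·sqrt(λ).  Maximum diameters are the largest
pairwise distances between boundary-mesh vertices, in 3D and in the three
orthogonal projection planes (slice = row-column plane, column = row-slice,
row = column-slice).

Degenerate ROIs (a single voxel, or coplanar voxels) yield zero minor axes
and zero elongation/flatness rather than an error.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

from .manifest import SHAPE_FEATURES

__all__ = ["shape_features"]


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]  # (F, 3, 3)
    return float(abs(np.einsum("fi,fi->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0))


def _max_pairwise(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return 0.0
    pts = np.unique(np.round(points, 9), axis=0)
    if pts.shape[0] > 3 and pts.shape[1] <= 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (flat) point set: fall back to all points
    if pts.shape[0] > 2500:  # pragma: no cover - very large meshes
        sel = np.linspace(0, pts.shape[0] - 1, 2500).astype(int)
        pts = pts[sel]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """The 14 morphology descriptors of a binary 3D mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("empty mask")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    spacing = tuple(float(s) for s in spacing)

    n = int(mask.sum())
    voxel_volume = float(np.prod(spacing))
    verts, faces = _mesh(mask, spacing)
    area = float(mesh_surface_area(verts, faces))
    volume = _mesh_volume(verts, faces)
    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area if area > 0 else 0.0

    coords = np.column_stack(np.nonzero(mask)).astype(np.float64) * spacing
    if n > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    out = {
        "MeshVolume": volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume if volume > 0 else 0.0,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_pairwise(verts),
        "Maximum2DDiameterSlice": _max_pairwise(verts[:, (1, 2)]),
        "Maximum2DDiameterColumn": _max_pairwise(verts[:, (0, 1)]),
        "Maximum2DDiameterRow": _max_pairwise(verts[:, (0, 2)]),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
    assert tuple(out) == SHAPE_FEATURES
    return out
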