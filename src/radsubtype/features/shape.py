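"""3D shape descriptors of a binary tumor mask.

The 14 descriptors cover size (mesh and voxel volume), boundary
complexity (surface area, surface-to-volume ratio, sphericity),
extent (maximum 3D diameter and the three orthogonal-plane maximum
2D diameters) and moment-based geometry (principal axis lengths,
elongation, flatness). Surface quantities come from a marching-cubes
triangulation of the mask; axis lengths from the eigenvalues of the
physical-coordinate covariance of the mask voxels (length =
4*sqrt(lambda), the full extent of an ellipsoid with matching
second moments).

Degenerate masks are defined rather than rejected: a single voxel has
all diameters 0, elongation and flatness 1.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes

from radsubtype.maps import VOIMask

SHAPE_FEATURE_NAMES = (
    "mesh_volume",
    "voxel_volume",
    "surface_area",
    "surface_volume_ratio",
    "sphericity",
    "maximum_3d_diameter",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "maximum_2d_diameter_slice",
    "maximum_2d_diameter_row",
    "maximum_2d_diameter_column",
)

__all__ = ["shape_features", "SHAPE_FEATURE_NAMES"]


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    """Marching-cubes triangulation of the padded mask at level 0.5.

    The binary mask is pre-filtered with a small Gaussian (sigma 0.8
    voxels) before meshing: the raw 0/1 staircase inflates the surface
    area of smooth objects by ~9%, while the anti-aliased isosurface
    is within ~1% on a digital ball. Masks too small to survive the
    filter fall back to the unfiltered mesh.
    """
    padded = np.pad(mask.astype(np.float64), 2)
    smoothed = gaussian_filter(padded, sigma=0.8)
    source = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = marching_cubes(source, level=0.5, spacing=spacing)
    return verts.astype(np.float64), faces

def _mesh_area_volume(verts: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    cross = np.cross(b - a, c - a)
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    # divergence theorem; orientation consistent up to a global sign
    volume = abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)
    return float(area), float(volume)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance, via the convex hull when
    possible (the diameter is attained on hull vertices)."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 10 and points.shape[1] <= 3:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:  # degenerate (coplanar/collinear) sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: VOIMask) -> dict[str, float]:
    """Compute the 14 shape features of a mask at isotropic spacing.

    The three maximum 2D diameters are the largest in-plane extents
    over planes normal to axis 2 (slice), axis 0 (row) and axis 1
    (column) respectively.
    """
    if mask.empty:
        raise ValueError("cannot compute shape features of an empty mask")
    spacing = mask.spacing_mm
    m = mask.mask
    n_vox = mask.voxel_count
    voxel_volume = n_vox * float(np.prod(spacing))

    verts, faces = _mesh(m, spacing)
    surface_area, mesh_volume = _mesh_area_volume(verts, faces)
    svr = surface_area / mesh_volume if mesh_volume > 0 else float("inf")
    sphericity = (
        (36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / surface_area
        if surface_area > 0 else 0.0
    )

    coords = np.argwhere(m).astype(float) * np.asarray(spacing)
    if n_vox > 1:
        cov = np.cov(coords, rowvar=False, ddof=0)
        eigvals = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0

    max3d = _max_pairwise(coords)

    def max2d(drop_axis: int) -> float:
        keep = [ax for ax in range(3) if ax != drop_axis]
        best = 0.0
        idx = np.argwhere(m)
        for plane in np.unique(idx[:, drop_axis]):
            pts = idx[idx[:, drop_axis] == plane][:, keep].astype(float)
            pts *= np.asarray([spacing[ax] for ax in keep])
            best = max(best, _max_pairwise(pts))
        return best

    return {
        "mesh_volume": mesh_volume,
        "voxel_volume": voxel_volume,
        "surface_area": surface_area,
        "surface_volume_ratio": svr,
        "sphericity": sphericity,
        "maximum_3d_diameter": max3d,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elongation,
        "flatness": flatness,
        "maximum_2d_diameter_slice": max2d(2),
        "maximum_2d_diameter_row": max2d(0),
        "maximum_2d_diameter_column": max2d(1),
    }
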