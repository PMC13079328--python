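"""3D binary morphology: connected components, cross-kernel erosion,
boundary shells, centroids and volumes.

Lesion boundaries are defined voxel-wise: one erosion with the 6-connected
cross structuring element, subtracted from the original mask, leaves the
mask's inner surface layer.  Component extraction defaults to full 26
adjacency because perivascular spaces are thin oblique tubules that
fragment under face-only connectivity; the choice is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid3D

__all__ = [
    "LesionComponent",
    "connected_components",
    "label_components",
    "erode_cross",
    "boundary_shell",
    "component_centroid",
    "mask_volume_mm3",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LesionComponent:
    """One connected component of a binary mask.

    ``centroid_mm`` is the unweighted mean of voxel indices scaled by the
    voxel spacing (world = index x spacing); masks are binary so there is
    no intensity weighting.
    """

    component_id: int
    voxel_indices: np.ndarray  # (n, 3) int array
    voxel_count: int
    volume_mm3: float
    centroid_mm: tuple[float, float, float]


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTS[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}") from None


def label_components(mask: VoxelGrid3D, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label connected components; labels are assigned deterministically in
    raster-scan order of each component's first voxel."""
    mask.require_binary()
    return ndimage.label(mask.astype_bool(), structure=_structure(connectivity))


def connected_components(mask: VoxelGrid3D, connectivity: int = 26) -> list[LesionComponent]:
    """Extract all connected components of a binary mask.

    Every foreground voxel belongs to exactly one component; ids start at 1
    and are ordered by the lexicographically first voxel of each component.
    """
    labels, n = label_components(mask, connectivity)
    if n == 0:
        return []
    coords = np.argwhere(labels > 0)
    lab = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    order = np.argsort(lab, kind="stable")
    coords = coords[order]
    lab = lab[order]
    splits = np.searchsorted(lab, np.arange(2, n + 1))
    spacing = np.asarray(mask.spacing_mm)
    vox_vol = mask.voxel_volume_mm3
    components = []
    for cid, vox in enumerate(np.split(coords, splits), start=1):
        centroid = vox.mean(axis=0) * spacing
        components.append(
            LesionComponent(
                component_id=cid,
                voxel_indices=vox,
                voxel_count=len(vox),
                volume_mm3=len(vox) * vox_vol,
                centroid_mm=tuple(float(c) for c in centroid),
            )
        )
    return components


def erode_cross(mask: VoxelGrid3D) -> VoxelGrid3D:
    """One erosion with the 6-connected cross kernel.

    A voxel survives iff it and all six face neighbours are foreground;
    outside the array counts as background, so border voxels never survive.
    """
    mask.require_binary()
    eroded = ndimage.binary_erosion(mask.astype_bool(), structure=_STRUCTS[6], border_value=0)
    return mask.like(eroded.astype(np.uint8))


def boundary_shell(mask: VoxelGrid3D) -> VoxelGrid3D:
    """Inner surface layer: the mask minus its cross-kernel erosion."""
    eroded = erode_cross(mask)
    shell = mask.astype_bool() & ~eroded.astype_bool()
    return mask.like(shell.astype(np.uint8))


def component_centroid(
    voxel_indices: np.ndarray, spacing_mm: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Unweighted centroid of voxel indices in world (mm) coordinates."""
    vox = np.asarray(voxel_indices, dtype=float)
    if vox.size == 0:
        raise ValueError("cannot take the centroid of an empty component")
    c = vox.reshape(-1, 3).mean(axis=0) * np.asarray(spacing_mm)
    return (float(c[0]), float(c[1]), float(c[2]))


def mask_volume_mm3(mask: VoxelGrid3D) -> float:
    """Foreground voxel count times voxel volume."""
    mask.require_binary()
    return mask.foreground_count() * mask.voxel_volume_mm3
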