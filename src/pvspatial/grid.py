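"""Voxel grid container and geometric consistency checks.

Every mask and label volume in the pipeline is represented as a
:class:`VoxelGrid3D`: a 3D integer lattice with per-axis voxel spacing in
millimetres.  All geometry downstream (centroids, distances, volumes) is
computed in axis-aligned index space scaled by the spacing; the rotational
part of a NIfTI affine is deliberately ignored, since within-subject
distances between coregistered same-grid masks are invariant to a rigid
reorientation of the whole volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid3D", "GeometryReport", "check_geometry"]

#: per-axis spacing agreement tolerance (mm) used by :func:`check_geometry`
SPACING_TOL_MM = 1e-4


@dataclass
class VoxelGrid3D:
    """A 3D scalar/binary image on a regular grid.

    Parameters
    ----------
    values
        3D integer array.  Binary masks are restricted to {0, 1}.
    spacing_mm
        Positive voxel edge lengths (mm) along each axis.
    label_meaning
        Optional map from integer label to region name (label volumes only).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_meaning: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"degenerate shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def is_binary(self) -> bool:
        if self.values.dtype == bool:
            return True
        if np.issubdtype(self.values.dtype, np.integer):
            return bool(self.values.min() >= 0 and self.values.max() <= 1)
        return bool(np.isin(self.values, (0, 1)).all())

    def require_binary(self, name: str = "mask") -> None:
        if not self.is_binary():
            bad = np.setdiff1d(np.unique(self.values), [0, 1])[:5]
            raise ValueError(f"{name} is not binary; found values {bad.tolist()}")

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.values))

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def like(self, values: np.ndarray) -> "VoxelGrid3D":
        """New grid with the same geometry but different values."""
        return VoxelGrid3D(values, self.spacing_mm)


@dataclass
class GeometryReport:
    """Result of a cross-mask geometric consistency check."""

    ok: bool
    messages: list[str]

    def __bool__(self) -> bool:
        return self.ok


def check_geometry(grids: list[VoxelGrid3D], spacing_tol_mm: float = SPACING_TOL_MM) -> GeometryReport:
    """Check that all grids share one shape and (within tolerance) one spacing.

    Report-valued: never raises for mismatches, names the offending axis.
    """
    if len(grids) < 2:
        raise ValueError("need at least two grids to compare")
    ref = grids[0]
    messages: list[str] = []
    for i, g in enumerate(grids[1:], start=1):
        for ax in range(3):
            if g.shape[ax] != ref.shape[ax]:
                messages.append(
                    f"grid {i}: shape mismatch on axis {ax}: {g.shape[ax]} != {ref.shape[ax]}"
                )
            if abs(g.spacing_mm[ax] - ref.spacing_mm[ax]) > spacing_tol_mm:
                messages.append(
                    f"grid {i}: spacing mismatch on axis {ax}: "
                    f"{g.spacing_mm[ax]} != {ref.spacing_mm[ax]} (tol {spacing_tol_mm} mm)"
                )
    return GeometryReport(ok=not messages, messages=messages)
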