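"""Analysis region masks and per-region EPVS burden metrics.

Five binary regions drive the regional analysis: whole brain (WB), white
matter (WM), basal ganglia (BG), the lesion mask itself (WML) and its
complement within the brain (non-WML).  Regions are built either from an
integer label volume in the FreeSurfer aseg colour-table convention or
from caller-supplied binary masks.

Regional EPVS counts follow the intersect-then-count rule: the EPVS mask
is intersected with the region and connected components of the
intersection are counted.  A component straddling a region border
therefore contributes to both regions, so regional counts are NOT a
partition of the whole-brain count.  A centroid-assignment alternative
(each component assigned to the single region containing its centroid
voxel) is available via ``assignment="centroid"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid3D
from .morphology import connected_components, label_components

__all__ = [
    "RegionSet",
    "SubjectMetrics",
    "DEFAULT_LABEL_CONFIG",
    "build_region_set",
    "regional_epvs_metrics",
    "normalize_by_icv",
]

REGION_NAMES = ("wb", "wm", "bg", "wml", "non_wml")

# FreeSurfer aseg colour-table ids: left/right thalamus, caudate, putamen,
# pallidum, accumbens for BG; left/right cerebral white matter for WM.
DEFAULT_LABEL_CONFIG: dict[str, list[int]] = {
    "bg": [10, 11, 12, 13, 26, 49, 50, 51, 52, 58],
    "wm": [2, 41],
}


@dataclass
class RegionSet:
    """The five analysis regions on one voxel grid."""

    wb: VoxelGrid3D
    wm: VoxelGrid3D
    bg: VoxelGrid3D
    wml: VoxelGrid3D
    non_wml: VoxelGrid3D

    def __getitem__(self, name: str) -> VoxelGrid3D:
        if name not in REGION_NAMES:
            raise KeyError(f"unknown region {name!r}; expected one of {REGION_NAMES}")
        return getattr(self, name)


@dataclass
class SubjectMetrics:
    """One row of per-subject regional burden metrics."""

    subject_id: str
    icv_mm3: float
    epvs_count: dict[str, int]
    epvs_volume_mm3: dict[str, float]
    epvs_volume_pct_icv: dict[str, float]
    wml_volume_mm3: float
    wml_volume_pct_icv: float
    bin_counts: dict[str, int] = field(default_factory=dict)
    has_wml: bool = True


def build_region_set(
    region_source: VoxelGrid3D | dict[str, VoxelGrid3D],
    wml_mask: VoxelGrid3D,
    label_config: dict[str, list[int]] | None = None,
) -> RegionSet:
    """Build the five analysis regions.

    ``region_source`` is either an integer label volume (aseg-style) or a
    dict of binary masks with keys ``wm`` and ``bg`` (optional ``wb``;
    default WB = WM union BG).  Configured label ids absent from the
    volume simply contribute nothing.
    """
    cfg = {**DEFAULT_LABEL_CONFIG, **(label_config or {})}
    wml_mask.require_binary("wml mask")
    if isinstance(region_source, VoxelGrid3D):
        labels = region_source.values
        wb = labels != 0
        bg = np.isin(labels, cfg["bg"])
        wm = np.isin(labels, cfg["wm"])
        like = region_source
    else:
        wm_g = region_source["wm"]
        bg_g = region_source["bg"]
        wm_g.require_binary("wm mask")
        bg_g.require_binary("bg mask")
        wm = wm_g.astype_bool()
        bg = bg_g.astype_bool()
        wb = region_source["wb"].astype_bool() if "wb" in region_source else (wm | bg)
        like = wm_g
    wml = wml_mask.astype_bool()
    non_wml = wb & ~wml
    as_grid = lambda a: like.like(a.astype(np.uint8))
    return RegionSet(
        wb=as_grid(wb), wm=as_grid(wm), bg=as_grid(bg), wml=as_grid(wml), non_wml=as_grid(non_wml)
    )


def regional_epvs_metrics(
    epvs_mask: VoxelGrid3D,
    region_mask: VoxelGrid3D,
    connectivity: int = 26,
    assignment: str = "intersection",
) -> tuple[int, float]:
    """Regional EPVS (count, volume_mm3).

    ``assignment="intersection"``: intersect the EPVS mask with the region,
    then count components of the intersection and sum its volume (straddling
    components split/double-count; the default, region-literal rule).
    ``assignment="centroid"``: count whole-mask components whose centroid's
    nearest voxel lies in the region; volume is still that of the
    intersected voxels.
    """
    epvs_mask.require_binary("epvs mask")
    region_mask.require_binary("region mask")
    inter = epvs_mask.astype_bool() & region_mask.astype_bool()
    volume = float(inter.sum()) * epvs_mask.voxel_volume_mm3
    if assignment == "intersection":
        _, count = label_components(epvs_mask.like(inter.astype(np.uint8)), connectivity)
    elif assignment == "centroid":
        region = region_mask.astype_bool()
        spacing = np.asarray(epvs_mask.spacing_mm)
        count = 0
        for comp in connected_components(epvs_mask, connectivity):
            idx = np.rint(np.asarray(comp.centroid_mm) / spacing).astype(int)
            idx = np.clip(idx, 0, np.asarray(region.shape) - 1)
            if region[tuple(idx)]:
                count += 1
    else:
        raise ValueError(f"unknown assignment rule {assignment!r}")
    return int(count), volume


def normalize_by_icv(volume_mm3: float, icv_mm3: float) -> float:
    """Volume as a percentage of intracranial volume."""
    if not icv_mm3 > 0:
        raise ValueError(f"icv_mm3 must be positive, got {icv_mm3}")
    if volume_mm3 < 0:
        raise ValueError(f"volume_mm3 must be nonnegative, got {volume_mm3}")
    return 100.0 * volume_mm3 / icv_mm3
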