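"""NIfTI mask I/O and cohort manifest parsing.

The manifest is a UTF-8 CSV with header columns
``subject_id, epvs_mask, wml_mask, region_source, icv_mm3, age, sex,
diagnosis, amyloid_suvr, tracer, apoe``.  Optional fields (amyloid_suvr,
tracer, apoe, region_source) may be empty.  Parsing is strict by default:
a malformed row aborts the read, because silently dropping subjects would
shrink the cohort and bias every downstream group statistic.  Lenient mode
logs and skips bad rows instead.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VoxelGrid3D

__all__ = [
    "CohortRecord",
    "ManifestError",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "subject_id",
    "epvs_mask",
    "wml_mask",
    "region_source",
    "icv_mm3",
    "age",
    "sex",
    "diagnosis",
    "amyloid_suvr",
    "tracer",
    "apoe",
]

VALID_SEX = {"female", "male"}
VALID_DIAGNOSIS = {"CU", "MCI", "AD"}
VALID_TRACER = {"FBP", "FBB"}
VALID_ALLELES = {"e2", "e3", "e4"}


class ManifestError(ValueError):
    """Raised for malformed cohort manifests (strict mode)."""


@dataclass
class CohortRecord:
    """One subject row of the cohort manifest."""

    subject_id: str
    epvs_mask_path: str
    wml_mask_path: str
    region_source_path: str | None
    icv_mm3: float
    age_years: float
    sex: str
    diagnosis: str
    amyloid_suvr: float | None = None
    tracer: str | None = None
    apoe_genotype: tuple[str, str] | None = None


def read_mask(path: str | os.PathLike, expect_binary: bool = False) -> VoxelGrid3D:
    """Read a NIfTI volume as a :class:`VoxelGrid3D`.

    Spacing is taken from the header zooms.  With ``expect_binary`` any
    nonzero voxel is mapped to 1.  Rejects non-3D volumes and non-positive
    spacings with a diagnostic.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    if expect_binary:
        data = (data != 0).astype(np.uint8)
    else:
        data = np.rint(data).astype(np.int32)
    return VoxelGrid3D(data, spacing)


def write_mask(grid: VoxelGrid3D, path: str | os.PathLike) -> None:
    """Write a grid as NIfTI-1 with a diagonal affine built from the spacing."""
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    dtype = np.uint8 if grid.is_binary() else np.int32
    img = nib.Nifti1Image(grid.values.astype(dtype), affine)
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))


def parse_apoe(text: str) -> tuple[str, str]:
    """Parse an APOE genotype like ``e3/e4`` (ε accepted) into an allele pair."""
    cleaned = text.strip().lower().replace("ε", "e")
    parts = [p.strip() for p in cleaned.replace(",", "/").split("/") if p.strip()]
    if len(parts) != 2 or any(p not in VALID_ALLELES for p in parts):
        raise ValueError(f"malformed APOE genotype: {text!r}")
    return (parts[0], parts[1])


def _parse_row(row: pd.Series, rownum: int) -> CohortRecord:
    def bad(col: str, why: str) -> ManifestError:
        return ManifestError(f"manifest row {rownum}, column '{col}': {why}")

    def opt(col: str) -> str | None:
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        v = str(v).strip()
        return v or None

    sid = opt("subject_id")
    if not sid:
        raise bad("subject_id", "missing")
    try:
        icv = float(row["icv_mm3"])
    except (TypeError, ValueError):
        raise bad("icv_mm3", f"not numeric: {row['icv_mm3']!r}") from None
    if not icv > 0:
        raise bad("icv_mm3", f"must be positive, got {icv}")
    try:
        age = float(row["age"])
    except (TypeError, ValueError):
        raise bad("age", f"not numeric: {row['age']!r}") from None
    sex = (opt("sex") or "").lower()
    if sex not in VALID_SEX:
        raise bad("sex", f"unknown code {row.get('sex')!r}")
    diagnosis = (opt("diagnosis") or "").upper()
    if diagnosis not in VALID_DIAGNOSIS:
        raise bad("diagnosis", f"unknown code {row.get('diagnosis')!r}")

    suvr_text = opt("amyloid_suvr")
    suvr = None
    if suvr_text is not None:
        try:
            suvr = float(suvr_text)
        except ValueError:
            raise bad("amyloid_suvr", f"not numeric: {suvr_text!r}") from None
    tracer = opt("tracer")
    if tracer is not None:
        tracer = tracer.upper()
        if tracer not in VALID_TRACER:
            raise bad("tracer", f"unknown tracer {tracer!r}")
    if suvr is not None and tracer is None:
        raise bad("tracer", "tracer required when amyloid_suvr present")
    apoe_text = opt("apoe")
    apoe = None
    if apoe_text is not None:
        try:
            apoe = parse_apoe(apoe_text)
        except ValueError as e:
            raise bad("apoe", str(e)) from None

    return CohortRecord(
        subject_id=sid,
        epvs_mask_path=opt("epvs_mask") or "",
        wml_mask_path=opt("wml_mask") or "",
        region_source_path=opt("region_source"),
        icv_mm3=icv,
        age_years=age,
        sex=sex,
        diagnosis=diagnosis,
        amyloid_suvr=suvr,
        tracer=tracer,
        apoe_genotype=apoe,
    )


def read_manifest(path: str | os.PathLike, strict: bool = True) -> list[CohortRecord]:
    """Read a cohort manifest CSV into :class:`CohortRecord` rows.

    Row numbers in diagnostics refer to data rows (header = row 0).  In
    strict mode (default) the first malformed row raises
    :class:`ManifestError`; in lenient mode bad rows are logged and skipped.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing required columns: {missing}")
    records: list[CohortRecord] = []
    seen: dict[str, int] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            rec = _parse_row(row, i)
            if rec.subject_id in seen:
                raise ManifestError(
                    f"manifest row {i}: duplicate subject_id {rec.subject_id!r} "
                    f"(first seen at row {seen[rec.subject_id]})"
                )
        except ManifestError as e:
            if strict:
                raise
            logger.warning("skipping manifest row %d: %s", i, e)
            continue
        seen[rec.subject_id] = i
        records.append(rec)
    return records


def write_manifest(records: list[CohortRecord], path: str | os.PathLike) -> None:
    """Write records back to the standard manifest CSV layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "epvs_mask": r.epvs_mask_path,
                "wml_mask": r.wml_mask_path,
                "region_source": r.region_source_path or "",
                "icv_mm3": r.icv_mm3,
                "age": r.age_years,
                "sex": r.sex,
                "diagnosis": r.diagnosis,
                "amyloid_suvr": "" if r.amyloid_suvr is None else r.amyloid_suvr,
                "tracer": r.tracer or "",
                "apoe": "/".join(r.apoe_genotype) if r.apoe_genotype else "",
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
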