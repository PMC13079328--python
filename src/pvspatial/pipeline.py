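"""Cohort orchestration: masks -> per-subject metrics -> statistical tables.

``run_metrics`` turns a cohort (a manifest of NIfTI paths or an in-memory
simulated cohort) into one tidy row per subject: regional EPVS counts and
volumes, ICV-normalized burdens, lesion volume, distance-bin histogram and
a has-WML flag.  Per-subject failures are logged and skipped by default so
one corrupt subject cannot abort a cohort run; strict mode re-raises.

``run_stats`` fits the analysis battery on the joined metrics/manifest
table: group comparisons per region (NB counts, ZINB within lesions,
log-Gaussian volumes), lesion-volume associations and interactions,
per-bin group models and per-bin lesion-volume models, each BH-FDR
adjusted within its own hypothesis family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VoxelGrid3D, check_geometry
from .mask_io import CohortRecord, read_manifest, read_mask
from .morphology import boundary_shell, connected_components, mask_volume_mm3
from .regions import (
    REGION_NAMES,
    SubjectMetrics,
    build_region_set,
    normalize_by_icv,
    regional_epvs_metrics,
)
from .spatial_coupling import BIN_LABELS, subject_distance_profile
from .stat_models import (
    GroupModelResult,
    ModelSpec,
    apply_fdr,
    fit_count_model,
    fit_log_volume_model,
    results_to_frame,
)
from .synthetic import CohortSim

__all__ = ["compute_subject_metrics", "run_metrics", "run_stats", "AnalysisSpec"]

logger = logging.getLogger(__name__)


def compute_subject_metrics(
    subject_id: str,
    epvs: VoxelGrid3D,
    wml: VoxelGrid3D,
    region_source,
    icv_mm3: float,
    connectivity: int = 26,
    label_config: dict | None = None,
    compute_distances: bool = True,
) -> SubjectMetrics:
    """All regional and distance metrics for one subject."""
    report = check_geometry([epvs, wml] + ([region_source] if isinstance(region_source, VoxelGrid3D) else []))
    if not report:
        raise ValueError("geometry mismatch: " + "; ".join(report.messages))
    regions = build_region_set(region_source, wml, label_config)
    counts: dict[str, int] = {}
    volumes: dict[str, float] = {}
    pct: dict[str, float] = {}
    for name in REGION_NAMES:
        c, v = regional_epvs_metrics(epvs, regions[name], connectivity)
        counts[name] = c
        volumes[name] = v
        pct[name] = normalize_by_icv(v, icv_mm3)
    wml_vol = mask_volume_mm3(regions.wml)

    bin_counts = {b: 0 for b in BIN_LABELS}
    has_wml = bool(regions.wml.foreground_count())
    if compute_distances:
        comps = connected_components(epvs, connectivity)
        boundary = boundary_shell(regions.wml) if has_wml else None
        profile = subject_distance_profile(comps, regions.wml, boundary, subject_id=subject_id)
        bin_counts = profile.histogram
        has_wml = profile.has_wml
    return SubjectMetrics(
        subject_id=subject_id,
        icv_mm3=icv_mm3,
        epvs_count=counts,
        epvs_volume_mm3=volumes,
        epvs_volume_pct_icv=pct,
        wml_volume_mm3=wml_vol,
        wml_volume_pct_icv=normalize_by_icv(wml_vol, icv_mm3),
        bin_counts=bin_counts,
        has_wml=has_wml,
    )


def _metrics_row(m: SubjectMetrics) -> dict:
    row: dict = {"subject_id": m.subject_id, "icv_mm3": m.icv_mm3}
    for name in REGION_NAMES:
        row[f"epvs_count_{name}"] = m.epvs_count[name]
        row[f"epvs_volume_mm3_{name}"] = m.epvs_volume_mm3[name]
        row[f"epvs_volume_pct_icv_{name}"] = m.epvs_volume_pct_icv[name]
    row["wml_volume_mm3"] = m.wml_volume_mm3
    row["wml_volume_pct_icv"] = m.wml_volume_pct_icv
    for b in BIN_LABELS:
        row[f"bin_{b}"] = m.bin_counts.get(b, 0)
    row["has_wml"] = m.has_wml
    return row


def run_metrics(
    cohort: str | list[CohortRecord] | CohortSim,
    connectivity: int = 26,
    label_config: dict | None = None,
    strict: bool = False,
    compute_distances: bool = True,
) -> pd.DataFrame:
    """Per-subject metrics table for a cohort.

    ``cohort`` may be a manifest CSV path, a list of records (masks read
    from disk), or an in-memory :class:`CohortSim`.
    """
    rows = []
    if isinstance(cohort, CohortSim):
        items = [(s.record, s.epvs, s.wml, s.labels) for s in cohort.subjects]
    else:
        records = read_manifest(cohort) if isinstance(cohort, str) else cohort
        items = [(r, None, None, None) for r in records]
    if not items:
        raise ValueError("empty cohort")
    for rec, epvs, wml, labels in items:
        try:
            if epvs is None:
                epvs = read_mask(rec.epvs_mask_path, expect_binary=True)
                wml = read_mask(rec.wml_mask_path, expect_binary=True)
                labels = read_mask(rec.region_source_path)
            m = compute_subject_metrics(
                rec.subject_id, epvs, wml, labels, rec.icv_mm3,
                connectivity=connectivity, label_config=label_config,
                compute_distances=compute_distances,
            )
        except Exception:
            if strict:
                raise
            logger.exception("subject %s failed; skipping", rec.subject_id)
            continue
        rows.append(_metrics_row(m))
    return pd.DataFrame(rows)


def join_manifest(metrics: pd.DataFrame, records: list[CohortRecord] | pd.DataFrame) -> pd.DataFrame:
    """Join the metrics table to manifest covariates for modelling."""
    if isinstance(records, pd.DataFrame):
        man = records
    else:
        man = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "age": r.age_years,
                    "sex": r.sex,
                    "diagnosis": r.diagnosis,
                    "amyloid_suvr": r.amyloid_suvr,
                    "tracer": r.tracer,
                }
                for r in records
            ]
        )
    df = metrics.merge(man, on="subject_id", how="inner")
    with np.errstate(divide="ignore"):
        df["wml_log_volume"] = np.where(
            df["wml_volume_mm3"] > 0, np.log(df["wml_volume_mm3"]), np.nan
        )
    return df


@dataclass
class AnalysisSpec:
    """Which analysis tables to produce and how groups are coded."""

    group: str = "diagnosis"
    reference: str = "CU"
    covariates: tuple[str, ...] = ("age", "sex")
    regions: tuple[str, ...] = ("wb", "wm", "bg", "wml", "non_wml")
    bins: tuple[str, ...] = tuple(b for b in BIN_LABELS)
    wml_sensitivity: bool = True


def _safe_fit(fn, *args, **kwargs) -> list[GroupModelResult]:
    try:
        out = fn(*args, **kwargs)
        return out[0] if isinstance(out, tuple) else out
    except Exception as e:
        logger.warning("model fit failed (%s); skipping table rows", e)
        return []


def run_stats(
    metrics: pd.DataFrame,
    records: list[CohortRecord] | pd.DataFrame,
    spec: AnalysisSpec | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit the full analysis battery; returns named result tables.

    Tables: ``group_comparisons`` (per region, counts and volumes),
    ``wml_association`` (lesion log-volume as predictor, per region),
    ``interaction`` (lesion volume x group), ``bin_group`` (per-bin counts
    vs group), ``bin_wml`` (per-bin counts vs lesion log-volume) and, when
    enabled, ``bin_group_sensitivity`` (group models with lesion log-volume
    covariate).  Each table carries raw and family-wise BH-adjusted p.
    """
    spec = spec or AnalysisSpec()
    df = join_manifest(metrics, records)
    if spec.group not in df.columns:
        raise ValueError(f"grouping column {spec.group!r} missing from table")
    tables: dict[str, list[GroupModelResult]] = {}

    # group comparisons per region: counts (NB; ZINB within lesions) + volumes
    comp: list[GroupModelResult] = []
    for region in spec.regions:
        family = "ZINB" if region == "wml" else "NB"
        comp += _safe_fit(
            fit_count_model,
            df,
            ModelSpec(f"epvs_count_{region}", family, spec.group, spec.reference,
                      spec.covariates, family_id="group_comparisons"),
        )
        comp += _safe_fit(
            fit_log_volume_model,
            df,
            ModelSpec(f"epvs_volume_pct_icv_{region}", "GAUSSIAN_LOG_OUTCOME", spec.group,
                      spec.reference, spec.covariates, family_id="group_comparisons"),
        )
    tables["group_comparisons"] = comp

    # lesion-volume association + interaction, per region (subjects with WML)
    dfw = df.dropna(subset=["wml_log_volume"])
    assoc: list[GroupModelResult] = []
    inter: list[GroupModelResult] = []
    for region in spec.regions:
        base = ModelSpec(f"epvs_count_{region}", "NB", spec.group, spec.reference,
                         spec.covariates, wml_log_volume="wml_log_volume",
                         family_id="wml_association")
        assoc += _safe_fit(fit_count_model, dfw, base)
        inter += _safe_fit(
            fit_count_model, dfw,
            ModelSpec(f"epvs_count_{region}", "NB", spec.group, spec.reference,
                      spec.covariates, wml_log_volume="wml_log_volume",
                      interaction=True, family_id="interaction"),
        )
    tables["wml_association"] = assoc
    tables["interaction"] = inter

    # per-bin models
    bin_group: list[GroupModelResult] = []
    bin_wml: list[GroupModelResult] = []
    bin_sens: list[GroupModelResult] = []
    for b in spec.bins:
        col = f"bin_{b}"
        bin_group += [
            r for r in _safe_fit(
                fit_count_model, df,
                ModelSpec(col, "NB", spec.group, spec.reference, spec.covariates,
                          family_id="bin_group"),
            )
        ]
        bin_wml += [
            r for r in _safe_fit(
                fit_count_model, dfw,
                ModelSpec(col, "NB", group=None, reference=None, covariates=spec.covariates,
                          wml_log_volume="wml_log_volume", family_id="bin_wml"),
            )
        ]
        if spec.wml_sensitivity:
            bin_sens += _safe_fit(
                fit_count_model, dfw,
                ModelSpec(col, "NB", spec.group, spec.reference, spec.covariates,
                          wml_log_volume="wml_log_volume", family_id="bin_group_sensitivity"),
            )
    tables["bin_group"] = bin_group
    tables["bin_wml"] = bin_wml
    if spec.wml_sensitivity:
        tables["bin_group_sensitivity"] = bin_sens

    out: dict[str, pd.DataFrame] = {}
    for name, results in tables.items():
        adjusted = apply_fdr(results)
        frame = results_to_frame(adjusted)
        out[name] = frame
    return out


def per_bin_wml_coefficients(
    metrics: pd.DataFrame,
    records: list[CohortRecord] | pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    bins: tuple[str, ...] = ("B5", "B10", "B15", "B20", "B25", "B30", "OVER30"),
) -> pd.DataFrame:
    """Per-distance-bin NB coefficient of lesion log-volume.

    One NB fit per bin: bin count ~ wml_log_volume + covariates, on
    subjects with lesions.  Returns a tidy frame ordered by bin, used to
    examine how the lesion-burden association decays with distance.
    """
    df = join_manifest(metrics, records).dropna(subset=["wml_log_volume"])
    rows = []
    for b in bins:
        try:
            results = fit_count_model(
                df,
                ModelSpec(f"bin_{b}", "NB", group=None, reference=None, covariates=covariates,
                          wml_log_volume="wml_log_volume", family_id="bin_wml"),
            )
        except ValueError:  # e.g. a distal bin empty across the whole cohort
            rows.append({"bin": b, "coefficient": np.nan, "beta_exp": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "converged": False})
            continue
        for r in results:
            if r.term == "wml_log_volume":
                rows.append({"bin": b, "coefficient": r.coefficient, "beta_exp": r.beta_exp,
                             "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p_value,
                             "converged": r.converged})
    return pd.DataFrame(rows)
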