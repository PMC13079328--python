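"""Synthetic cohorts of paired EPVS/WML masks with known ground truth.

The generator renders, per subject, a brain as an ellipsoid label volume
(aseg-style ids: cerebral white matter 2/41, basal ganglia blobs 11/50,
cortex 3/42), grows white-matter lesions from random WM seed voxels by
iterative stochastic dilation up to a lognormal target volume, and stamps
EPVS as thin random-orientation tubules at locations sampled with
placement intensity

    lambda(d) = 1 + A * exp(-d / tau)

where ``d`` is the exact Euclidean-distance-transform distance (mm) to
the WML boundary shell — so EPVS density decays with distance from
lesions.  Total per-subject EPVS counts are negative binomial with a
group log-rate structure and age/sex/lesion-volume terms.  Within-lesion
EPVS counts are zero-inflated: a structural zero with probability pi
(default 0.6, matching the observed share of subjects with no EPVS inside
lesions), otherwise a zero-truncated Poisson number of small tubules
confined to the lesion mask.

Tubules stamped outside lesions have any lesion-overlapping voxels
removed, keeping the EPVS and WML channels disjoint except for the
deliberately placed within-lesion EPVS.

Everything is reproducible: one master seed is split per subject with a
counter-based ``SeedSequence((seed, subject_index))`` scheme, so cohorts
are bit-identical under regeneration and safe to generate in parallel.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid3D
from .mask_io import CohortRecord, write_manifest, write_mask
from .morphology import boundary_shell, connected_components
from .spatial_coupling import BIN_LABELS, bin_distance

__all__ = [
    "GroupConfig",
    "SimulationConfig",
    "SubjectData",
    "CohortSim",
    "simulate_subject",
    "simulate_cohort",
    "simulate_counts",
]

ASEG_LABELS = {2: "wm_left", 41: "wm_right", 11: "bg_left", 50: "bg_right", 3: "cortex_left", 42: "cortex_right"}


@dataclass
class GroupConfig:
    """Study-condition parameters for one diagnostic group."""

    label: str
    n: int
    count_log_rate_offset: float = 0.0
    # lognormal parameters of WML volume as percent of ICV
    wml_pct_lognormal: tuple[float, float] = (-0.99, 0.8)
    coupling_amplitude: float = 4.0  # A >= 0
    coupling_scale_mm: float = 5.0  # tau > 0
    within_wml_zero_prob: float = 0.6  # pi
    zero_wml_prob: float = 0.0
    age_mean: float = 74.0
    age_sd: float = 8.0
    female_fraction: float = 0.52
    suvr_mean: float = 1.10
    suvr_sd: float = 0.18
    e4_allele_freq: float = 0.2

    def __post_init__(self) -> None:
        if self.coupling_amplitude < 0 or self.coupling_scale_mm <= 0:
            raise ValueError("coupling parameters: A >= 0, tau > 0")
        for p in (self.within_wml_zero_prob, self.zero_wml_prob, self.female_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings; defaults define the study conditions."""

    groups: list[GroupConfig]
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nb_dispersion: float = 0.5  # alpha
    count_intercept: float = math.log(120.0)
    age_log_slope_per_decade: float = 0.15
    male_log_offset: float = 0.1
    wml_count_log_slope: float = 0.2  # per unit ln(WML mm3), centred
    wml_log_volume_center: float = math.log(1500.0)
    within_wml_count_mean: float = 2.0  # zero-truncated Poisson mean parameter
    tubule_length_range: tuple[int, int] = (3, 8)
    within_tubule_length_range: tuple[int, int] = (2, 4)
    lesion_growth_keep_prob: float = 0.7
    max_lesions: int = 3
    record_bins: bool = True

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    @classmethod
    def default(cls, n_total: int = 500) -> "SimulationConfig":
        """Three diagnostic groups in the study cohort's proportions
        (CU:MCI:AD roughly 55:34:11) with Table-1-style demographics."""
        fracs = {"CU": 593 / 1080, "MCI": 369 / 1080, "AD": 118 / 1080}
        n_cu = round(n_total * fracs["CU"])
        n_mci = round(n_total * fracs["MCI"])
        n_ad = n_total - n_cu - n_mci
        sigma = 0.8
        mu = lambda mean_pct: math.log(mean_pct) - sigma**2 / 2
        groups = [
            GroupConfig("CU", n_cu, 0.0, (mu(0.51), sigma), age_mean=73.0, age_sd=8.1,
                        female_fraction=0.59, suvr_mean=1.05, e4_allele_freq=0.18),
            GroupConfig("MCI", n_mci, math.log(1.2), (mu(0.69), sigma), age_mean=74.7, age_sd=8.1,
                        female_fraction=0.44, suvr_mean=1.15, e4_allele_freq=0.22),
            GroupConfig("AD", n_ad, math.log(1.15), (mu(0.83), sigma), age_mean=77.1, age_sd=8.4,
                        female_fraction=0.43, suvr_mean=1.35, e4_allele_freq=0.45),
        ]
        return cls(groups=groups)


@dataclass
class SubjectData:
    """One simulated subject: masks, manifest record and truth row."""

    subject_id: str
    group: str
    epvs: VoxelGrid3D
    wml: VoxelGrid3D
    labels: VoxelGrid3D
    record: CohortRecord
    truth: dict


@dataclass
class CohortSim:
    """A simulated cohort (optionally materialized to disk)."""

    subjects: list[SubjectData]
    manifest: list[CohortRecord]
    truth: pd.DataFrame
    out_dir: str | None = None


# --------------------------------------------------------------------------
# cached anatomy: identical across subjects of one geometry

_GEOM_CACHE: dict = {}


def _anatomy(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    key = (shape, spacing)
    if key in _GEOM_CACHE:
        return _GEOM_CACHE[key]
    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.46 * np.asarray(shape)

    def ellipsoid(c, s):
        return (((idx[0] - c[0]) / s[0]) ** 2 + ((idx[1] - c[1]) / s[1]) ** 2 + ((idx[2] - c[2]) / s[2]) ** 2) <= 1.0

    brain = ellipsoid(center, semi)
    inner = ellipsoid(center, semi * 0.82)
    bg_off = 0.17 * shape[0]
    bg_semi = 0.10 * np.asarray(shape)
    bg_l = ellipsoid(center - np.array([bg_off, 0, 0]), bg_semi)
    bg_r = ellipsoid(center + np.array([bg_off, 0, 0]), bg_semi)
    bg = bg_l | bg_r
    wm = inner & ~bg
    cortex = brain & ~inner & ~bg
    left = idx[0] < center[0]
    labels = np.zeros(shape, dtype=np.int16)
    labels[wm & left] = 2
    labels[wm & ~left] = 41
    labels[bg_l] = 11
    labels[bg_r] = 50
    labels[cortex & left] = 3
    labels[cortex & ~left] = 42
    icv_mm3 = float(brain.sum()) * float(np.prod(spacing))
    out = {"brain": brain, "wm": wm, "bg": bg, "labels": labels, "icv_mm3": icv_mm3}
    _GEOM_CACHE[key] = out
    return out


def _grow_lesions(rng: np.random.Generator, wm: np.ndarray, target_voxels: int,
                  n_lesions: int, keep_prob: float) -> np.ndarray:
    """Grow lesion blobs from random WM seeds by stochastic dilation."""
    if target_voxels > 0.5 * wm.sum():
        raise ValueError("target WML volume exceeds available white matter")
    lesion = np.zeros(wm.shape, dtype=bool)
    wm_idx = np.argwhere(wm)
    shares = np.maximum(1, np.rint(rng.dirichlet(np.full(n_lesions, 3.0)) * target_voxels).astype(int))
    struct = ndimage.generate_binary_structure(3, 1)
    for share in shares:
        seed = wm_idx[rng.integers(len(wm_idx))]
        blob = np.zeros(wm.shape, dtype=bool)
        blob[tuple(seed)] = True
        vol = 1
        lo = seed.copy()
        hi = seed.copy() + 1
        while vol < share:
            lo = np.maximum(lo - 1, 0)
            hi = np.minimum(hi + 1, wm.shape)
            view = blob[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            cand = ndimage.binary_dilation(view, struct) & ~view
            cand &= wm[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            ci = np.argwhere(cand)
            if len(ci) == 0:
                break
            take = ci[rng.random(len(ci)) < keep_prob]
            if len(take) == 0:
                continue
            n_need = int(share - vol)
            if len(take) > n_need:
                take = take[rng.permutation(len(take))[:n_need]]
            view[take[:, 0], take[:, 1], take[:, 2]] = True
            vol += len(take)
        lesion |= blob
    return lesion


def _stamp_tubule(rng: np.random.Generator, mask: np.ndarray, center: np.ndarray,
                  length: int, allowed: np.ndarray) -> None:
    """Stamp a 1-voxel-thick tubule of given length through center,
    restricted to the allowed region."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    ts = np.arange(-(length - 1) / 2, (length - 1) / 2 + 1e-9, 0.4)
    pts = np.rint(center + np.outer(ts, u)).astype(int)
    np.clip(pts, 0, np.asarray(mask.shape) - 1, out=pts)
    keep = allowed[pts[:, 0], pts[:, 1], pts[:, 2]]
    pts = pts[keep]
    mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def _sample_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    k = 0
    while k == 0:
        k = int(rng.poisson(lam))
    return k


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return int(rng.poisson(lam))


def simulate_subject(
    config: SimulationConfig, group: GroupConfig, rng: np.random.Generator, subject_id: str
) -> SubjectData:
    """Simulate one subject's EPVS/WML masks, label volume and truth row."""
    anat = _anatomy(config.grid_shape, config.spacing_mm)
    spacing = np.asarray(config.spacing_mm)
    vox_vol = float(np.prod(spacing))
    shape = config.grid_shape

    age = float(rng.normal(group.age_mean, group.age_sd))
    is_female = bool(rng.random() < group.female_fraction)
    suvr = float(rng.normal(group.suvr_mean, group.suvr_sd))
    tracer = "FBP" if rng.random() < 0.5 else "FBB"
    alleles = tuple("e4" if rng.random() < group.e4_allele_freq else ("e2" if rng.random() < 0.1 else "e3") for _ in range(2))

    # ---- WML channel
    has_wml = rng.random() >= group.zero_wml_prob
    wml = np.zeros(shape, dtype=bool)
    if has_wml:
        pct = float(rng.lognormal(*group.wml_pct_lognormal))
        target_mm3 = pct / 100.0 * anat["icv_mm3"]
        n_lesions = int(rng.integers(1, config.max_lesions + 1))
        wml = _grow_lesions(
            rng, anat["wm"], max(1, int(round(target_mm3 / vox_vol))), n_lesions, config.lesion_growth_keep_prob
        )
    wml_volume_mm3 = float(wml.sum()) * vox_vol
    wml_grid = VoxelGrid3D(wml.astype(np.uint8), config.spacing_mm)

    # ---- placement weights: exact EDT distance to the lesion boundary shell
    eligible = (anat["wm"] | anat["bg"]) & ~wml
    elig_idx = np.argwhere(eligible)
    if wml.any():
        shell = boundary_shell(wml_grid).astype_bool()
        dist = ndimage.distance_transform_edt(~shell, sampling=config.spacing_mm)
        d_elig = dist[eligible]
        weights = 1.0 + group.coupling_amplitude * np.exp(-d_elig / group.coupling_scale_mm)
    else:
        weights = np.ones(len(elig_idx))

    # ---- total EPVS count: negative binomial with log-rate structure
    log_mu = (
        config.count_intercept
        + group.count_log_rate_offset
        + config.age_log_slope_per_decade * (age - 74.0) / 10.0
        + (0.0 if is_female else config.male_log_offset)
    )
    if wml.any():
        log_mu += config.wml_count_log_slope * (math.log(wml_volume_mm3) - config.wml_log_volume_center)
    n_epvs = _nb_draw(rng, math.exp(log_mu), config.nb_dispersion)

    epvs = np.zeros(shape, dtype=bool)
    allowed_out = anat["brain"] & ~wml
    if n_epvs > 0:
        # weighted sampling without replacement via Gumbel top-k
        keys = np.log(weights) + rng.gumbel(size=len(weights))
        take = min(n_epvs, len(keys))
        centers = elig_idx[np.argpartition(-keys, take - 1)[:take]]
        lmin, lmax = config.tubule_length_range
        for c in centers:
            _stamp_tubule(rng, epvs, c.astype(float), int(rng.integers(lmin, lmax + 1)), allowed_out)

    # ---- within-WML EPVS: zero-inflated count confined to the lesion mask
    within_structural_zero = bool(rng.random() < group.within_wml_zero_prob)
    n_within = 0
    if wml.any() and not within_structural_zero:
        n_within = _sample_truncated_poisson(rng, config.within_wml_count_mean)
        wml_idx = np.argwhere(wml)
        wmin, wmax = config.within_tubule_length_range
        for _ in range(n_within):
            c = wml_idx[rng.integers(len(wml_idx))]
            _stamp_tubule(rng, epvs, c.astype(float), int(rng.integers(wmin, wmax + 1)), wml)
    elif not wml.any():
        within_structural_zero = True

    epvs_grid = VoxelGrid3D(epvs.astype(np.uint8), config.spacing_mm)
    labels_grid = VoxelGrid3D(anat["labels"].copy(), config.spacing_mm, label_meaning=dict(ASEG_LABELS))

    truth: dict = {
        "subject_id": subject_id,
        "group": group.label,
        "age": age,
        "sex": "female" if is_female else "male",
        "icv_mm3": anat["icv_mm3"],
        "has_wml": bool(wml.any()),
        "wml_volume_mm3": wml_volume_mm3,
        "n_epvs_drawn": n_epvs,
        "n_within_drawn": n_within,
        "within_structural_zero": within_structural_zero,
        "coupling_amplitude": group.coupling_amplitude,
        "coupling_scale_mm": group.coupling_scale_mm,
    }
    if config.record_bins:
        truth.update(_true_bins(epvs_grid, wml_grid))

    record = CohortRecord(
        subject_id=subject_id,
        epvs_mask_path="",
        wml_mask_path="",
        region_source_path="",
        icv_mm3=anat["icv_mm3"],
        age_years=age,
        sex="female" if is_female else "male",
        diagnosis=group.label if group.label in {"CU", "MCI", "AD"} else "CU",
        amyloid_suvr=suvr,
        tracer=tracer,
        apoe_genotype=alleles,
    )
    return SubjectData(subject_id, group.label, epvs_grid, wml_grid, labels_grid, record, truth)


def _true_bins(epvs_grid: VoxelGrid3D, wml_grid: VoxelGrid3D) -> dict:
    """Ground-truth bin counts from realized components, via the exhaustive
    (brute-force) centroid-to-boundary distance — independent of the
    analyzer's expanding-window/KD-tree search path."""
    comps = connected_components(epvs_grid, connectivity=26)
    counts = {f"bin_{b}": 0 for b in BIN_LABELS}
    counts["n_components"] = len(comps)
    if not comps:
        return counts
    wml = wml_grid.astype_bool()
    spacing = np.asarray(wml_grid.spacing_mm)
    if wml.any():
        shell_pts = np.argwhere(boundary_shell(wml_grid).astype_bool()) * spacing
    for comp in comps:
        c = np.asarray(comp.centroid_mm)
        idx = np.rint(c / spacing).astype(int)
        inside = wml[tuple(np.clip(idx, 0, np.asarray(wml.shape) - 1))] if wml.any() else False
        if inside:
            counts["bin_WITHIN"] += 1
        elif not wml.any():
            counts["bin_OVER30"] += 1
        else:
            d = float(np.sqrt(((shell_pts - c) ** 2).sum(axis=1).min()))
            counts[f"bin_{bin_distance(d)}"] += 1
    return counts


def simulate_cohort(
    config: SimulationConfig, seed: int, out_dir: str | os.PathLike | None = None
) -> CohortSim:
    """Simulate a full cohort; optionally write NIfTI masks + CSVs.

    With ``out_dir`` set, writes ``<sid>_epvs.nii.gz``, ``<sid>_wml.nii.gz``,
    ``<sid>_labels.nii.gz`` per subject plus ``manifest.csv`` and
    ``truth.csv``, consumable by the pipeline unchanged.  Identical
    (config, seed) pairs produce byte-identical outputs.
    """
    subjects: list[SubjectData] = []
    counter = 0
    for group in config.groups:
        for _ in range(group.n):
            sid = f"S{counter:04d}"
            rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, counter))))
            subjects.append(simulate_subject(config, group, rng, sid))
            counter += 1
    truth = pd.DataFrame([s.truth for s in subjects])
    records = [s.record for s in subjects]
    if out_dir is not None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for s in subjects:
            s.record.epvs_mask_path = os.path.join(out_dir, f"{s.subject_id}_epvs.nii.gz")
            s.record.wml_mask_path = os.path.join(out_dir, f"{s.subject_id}_wml.nii.gz")
            s.record.region_source_path = os.path.join(out_dir, f"{s.subject_id}_labels.nii.gz")
            write_mask(s.epvs, s.record.epvs_mask_path)
            write_mask(s.wml, s.record.wml_mask_path)
            write_mask(s.labels, s.record.region_source_path)
        write_manifest(records, os.path.join(out_dir, "manifest.csv"))
        truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return CohortSim(subjects=subjects, manifest=records, truth=truth, out_dir=out_dir and str(out_dir))


def simulate_counts(
    seed: int,
    n_per_group: int = 200,
    rate_ratio: float = 1.0,
    alpha: float = 0.5,
    intercept: float = math.log(20.0),
    age_slope_per_decade: float = 0.15,
    male_offset: float = 0.1,
) -> pd.DataFrame:
    """Fast numeric two-group NB cohort (no mask rendering).

    Counts follow NB with log-mean ``intercept + log(rate_ratio)*[group B]
    + age and sex terms``; used for estimator calibration studies
    (coverage, type-I error) where mask geometry is irrelevant.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.repeat(["A", "B"], n_per_group)
    age = rng.normal(74.0, 8.0, n)
    sex = rng.choice(["female", "male"], n)
    log_mu = (
        intercept
        + np.log(rate_ratio) * (group == "B")
        + age_slope_per_decade * (age - 74.0) / 10.0
        + male_offset * (sex == "male")
    )
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.exp(log_mu))
    counts = rng.poisson(lam)
    return pd.DataFrame({"group": group, "age": age, "sex": sex, "count": counts})
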