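"""Generator determinism, calibration and generator/analyzer agreement."""

import numpy as np
import pytest
from scipy import stats as sps

from pvspatial.pipeline import run_metrics
from pvspatial.spatial_coupling import BIN_LABELS
from pvspatial.synthetic import (
    GroupConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_counts,
    simulate_subject,
)

SMALL = dict(grid_shape=(48, 48, 48))


def _one_group(n=4, **kw):
    return SimulationConfig(groups=[GroupConfig("G", n, **kw)], **SMALL)


def test_same_seed_bitwise_identical():
    a = simulate_cohort(_one_group(3), seed=123)
    b = simulate_cohort(_one_group(3), seed=123)
    for sa, sb in zip(a.subjects, b.subjects):
        assert np.array_equal(sa.epvs.values, sb.epvs.values)
        assert np.array_equal(sa.wml.values, sb.wml.values)
        assert sa.truth == sb.truth
    c = simulate_cohort(_one_group(3), seed=124)
    assert any(
        not np.array_equal(sa.epvs.values, sc.epvs.values) for sa, sc in zip(a.subjects, c.subjects)
    )


def test_cohort_bookkeeping_and_file_output(tmp_path):
    cfg = SimulationConfig(
        groups=[GroupConfig("CU", 2), GroupConfig("MCI", 2), GroupConfig("AD", 2)], **SMALL
    )
    sim = simulate_cohort(cfg, seed=5, out_dir=tmp_path)
    assert len(sim.manifest) == 6
    assert len(list(tmp_path.glob("*_epvs.nii.gz"))) == 6
    assert len(list(tmp_path.glob("*_wml.nii.gz"))) == 6
    assert (tmp_path / "manifest.csv").exists() and (tmp_path / "truth.csv").exists()
    # manifest is consumable by the pipeline unchanged
    metrics = run_metrics(str(tmp_path / "manifest.csv"), compute_distances=False)
    assert len(metrics) == 6


def test_zero_wml_group_flagged_downstream():
    cfg = _one_group(3, zero_wml_prob=1.0)
    sim = simulate_cohort(cfg, seed=2)
    metrics = run_metrics(sim)
    assert not metrics["has_wml"].any()
    assert (metrics["wml_volume_mm3"] == 0).all()
    assert (metrics[[f"bin_{b}" for b in BIN_LABELS[:-1]]].sum(axis=1) == 0).all()


def test_truth_bins_match_pipeline_histogram():
    """The generator's brute-force truth bins agree with the analyzer's
    KD-tree/window distance path for every subject."""
    sim = simulate_cohort(_one_group(5), seed=31)
    metrics = run_metrics(sim).set_index("subject_id")
    for s in sim.subjects:
        row = metrics.loc[s.subject_id]
        for b in BIN_LABELS:
            assert row[f"bin_{b}"] == s.truth[f"bin_{b}"], (s.subject_id, b)
        assert row["epvs_count_wb"] == s.truth["n_components"]


def test_uniform_placement_when_coupling_off():
    """With A=0, EPVS centres are uniform over eligible tissue, so the share
    of components within 10 mm of the lesion boundary matches the eligible
    volume share (chi-square goodness of fit over pooled subjects)."""
    from pvspatial.morphology import boundary_shell, connected_components
    from scipy import ndimage

    cfg = _one_group(25, coupling_amplitude=0.0, within_wml_zero_prob=1.0)
    sim = simulate_cohort(cfg, seed=77)
    near = far = 0
    exp_near = exp_far = 0.0
    for s in sim.subjects:
        wml = s.wml.astype_bool()
        if not wml.any():
            continue
        shell = boundary_shell(s.wml).astype_bool()
        dist = ndimage.distance_transform_edt(~shell)
        eligible = ((s.labels.values == 2) | (s.labels.values == 41)
                    | (s.labels.values == 11) | (s.labels.values == 50)) & ~wml
        p_near = float((dist[eligible] <= 10).mean())
        comps = connected_components(s.epvs)
        for c in comps:
            idx = tuple(np.clip(np.rint(np.asarray(c.centroid_mm)).astype(int), 0, 47))
            if dist[idx] <= 10:
                near += 1
            else:
                far += 1
        exp_near += p_near * len(comps)
        exp_far += (1 - p_near) * len(comps)
    chi2 = (near - exp_near) ** 2 / exp_near + (far - exp_far) ** 2 / exp_far
    assert sps.chi2.sf(chi2, 1) > 0.001


def test_group_rate_offset_recovered_by_nb_fit():
    """Counts drawn with a log(1.5) group offset recover beta_exp ~ 1.5."""
    from pvspatial.stat_models import ModelSpec, fit_count_model

    df = simulate_counts(seed=21, n_per_group=500, rate_ratio=1.5, alpha=0.5)
    results = fit_count_model(
        df, ModelSpec("count", "NB", group="group", reference="A", covariates=("age", "sex"))
    )
    group = next(r for r in results if r.term == "group[B]")
    assert group.converged
    assert group.beta_exp == pytest.approx(1.5, rel=0.15)


def test_excessive_wml_target_raises():
    cfg = _one_group(1)
    cfg.groups[0].wml_pct_lognormal = (np.log(60.0), 1e-9)  # 60% of ICV
    with pytest.raises(ValueError, match="exceeds"):
        rng = np.random.Generator(np.random.Philox(1))
        simulate_subject(cfg, cfg.groups[0], rng, "S0")


def test_config_validation():
    with pytest.raises(ValueError, match="unique"):
        SimulationConfig(groups=[GroupConfig("A", 1), GroupConfig("A", 1)])
    with pytest.raises(ValueError, match="tau"):
        GroupConfig("A", 1, coupling_scale_mm=0.0)
    with pytest.raises(ValueError, match="positive"):
        SimulationConfig(groups=[GroupConfig("A", 1)], nb_dispersion=0.0)
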