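"""Generator self-checks: phantom anatomy, closed-form Jacobians, kinetics,
dose constraints and pathology sampling."""

import numpy as np
import pytest

from lungfx.core_io import CT_AIR_HU, ROIMask
from lungfx.perfusion import compute_metrics, extract_curve
from lungfx.roi_dose import ContourAssignment, DoseLevel, FedStatus, sphere_mask
from lungfx.synthetic import (
    ExpansionModel,
    KineticModel,
    PathologyEffectModel,
    PhantomSpec,
    SpecError,
    build_expansion_target,
    make_breathing_series,
    make_contrast_study,
    make_dose,
    make_lung_phantom,
    make_pathology,
    annotate_tree_doses,
)
from lungfx.ventilation import jacobian_map, ler_n, roi_ventilation


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------

def test_phantom_construction_checks(small_phantom):
    ph = small_phantom
    assert not (ph.lung_right & ph.lung_left).any()
    assert not (ph.vessel_mask & ~ph.lungs).any()  # vessels live inside lungs
    # HU modes near the design values per tissue label
    data = ph.image.data
    outside = ~sphere_mask(ph.image, (96, 96, 96), 95.0)
    assert np.median(data[outside]) == CT_AIR_HU
    assert abs(np.mean(data[ph.parenchyma]) - (-750.0)) < 15.0
    assert np.all(data[ph.vessel_mask] == 50.0)


def test_phantom_same_seed_is_identical():
    a = make_lung_phantom(PhantomSpec(shape=(32, 32, 32), seed=11))
    b = make_lung_phantom(PhantomSpec(shape=(32, 32, 32), seed=11))
    np.testing.assert_array_equal(a.image.data, b.image.data)
    assert a.tree.to_json() == b.tree.to_json()
    c = make_lung_phantom(PhantomSpec(shape=(32, 32, 32), seed=12))
    assert not np.array_equal(a.image.data, c.image.data)


def test_phantom_rejects_overlapping_lungs():
    with pytest.raises(SpecError):
        PhantomSpec(lung_centres_mm=((90.0, 96.0, 96.0), (100.0, 96.0, 96.0)))


# --------------------------------------------------------------------------
# breathing series
# --------------------------------------------------------------------------

def test_static_target_gives_zero_fields_and_identical_phases(small_phantom):
    ref = small_phantom.image
    target = ref.like(np.ones(ref.shape))
    study = make_breathing_series(small_phantom, target, n_phases=3)
    for f in study.true_fields:
        np.testing.assert_allclose(f.vectors, 0.0, atol=1e-12)
    for ph in study.series.phases[1:]:
        np.testing.assert_allclose(ph.data, ref.data, atol=1e-9)


def test_uniform_target_yields_analytic_peak_jacobian(small_phantom):
    model = ExpansionModel()
    ref = small_phantom.image
    target_data = np.where(small_phantom.lungs, 1.331, 1.0)
    target = ref.like(target_data)
    study = make_breathing_series(small_phantom, target, n_phases=2, model=model,
                                  generate_images=False)
    peak_j = study.true_jacobians[-1].data
    lungs_core = small_phantom.lungs & (np.abs(target_data - 1.331) < 1e-12)
    assert np.allclose(peak_j[lungs_core], 1.331, rtol=0.02)
    # numeric jacobian of the shipped field agrees with the analytic one
    # away from the lung boundary (where the step target is discontinuous)
    from scipy.ndimage import binary_erosion

    numeric = jacobian_map(study.true_fields[-1]).data
    interior = binary_erosion(lungs_core, iterations=2)
    rel = np.abs(numeric[interior] - peak_j[interior]) / peak_j[interior]
    assert np.percentile(rel, 95) < 0.02


def test_lern_on_true_jacobians_recovers_target(small_phantom):
    model = ExpansionModel()
    lc = np.asarray(small_phantom.spec.lung_centres_mm[0])
    regions = [(tuple(lc + [0, -14, 25]), 1.30), (tuple(lc + [0, 14, -25]), 1.06)]
    target = build_expansion_target(small_phantom, model, regions)
    study = make_breathing_series(small_phantom, target, n_phases=10, model=model,
                                  generate_images=False)
    vmap = ler_n(study.true_jacobians)
    err = np.abs(vmap.data - target.data)[small_phantom.lungs]
    assert err.mean() < 0.02 * model.background


def test_waveform_zero_at_exhale_unit_at_peak():
    w = ExpansionModel().waveform(10)
    assert w[0] == 0.0
    assert w.max() == pytest.approx(1.0)
    assert np.all((w >= 0) & (w <= 1))


# --------------------------------------------------------------------------
# contrast study
# --------------------------------------------------------------------------

def _vessel_roi(phantom, node, label="MD"):
    idx = phantom.vessel_voxels[node]
    mask = np.zeros(phantom.image.shape, dtype=bool)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return ROIMask(mask=mask, label=label, tissue="vessel")


def test_noiseless_peak_enhancement_recovers_amplitude(small_phantom):
    kin = KineticModel(noise_sd_hu=0.0)
    # dense sampling so a frame lands essentially on the bolus peak
    times = np.arange(0.0, 40.0, 0.25)
    series, effect = make_contrast_study(small_phantom, kin, times=times)
    node = max(small_phantom.vessel_voxels, key=lambda n: len(small_phantom.vessel_voxels[n]))
    curve = extract_curve(series, _vessel_roi(small_phantom, node), n_precontrast=8)
    metrics = compute_metrics(curve)
    assert effect[node] == 1.0
    assert metrics.peak_enhancement == pytest.approx(kin.amplitude_hu, rel=0.01)


def test_auc_effect_multiplier_recovered_noiseless(small_phantom):
    kin = KineticModel(noise_sd_hu=0.0, peak_loss_per_gy=0.0, fed_auc_multiplier=0.6,
                       subject_sd=0.0)
    dose = make_dose(small_phantom, "R0")
    annotate_tree_doses(small_phantom, dose)
    node = max(small_phantom.vessel_voxels, key=lambda n: len(small_phantom.vessel_voxels[n]))
    roi = _vessel_roi(small_phantom, node)
    # segment voxels at junctions are shared with child segments, so the
    # whole subtree carries the effect (as it does physiologically)
    fed = {node} | small_phantom.tree.descendants(node)
    pre, _ = make_contrast_study(small_phantom, kin, post=False)
    post, effect = make_contrast_study(small_phantom, kin, post=True, fed_nodes=fed)
    auc_pre = compute_metrics(extract_curve(pre, roi, 4)).auc
    auc_post = compute_metrics(extract_curve(post, roi, 4)).auc
    assert effect[node] == pytest.approx(0.6)
    assert auc_post / auc_pre == pytest.approx(0.6, abs=0.02)


def test_contrast_same_seed_identical(small_phantom):
    kin = KineticModel()
    a, _ = make_contrast_study(small_phantom, kin, rng=np.random.default_rng(5))
    b, _ = make_contrast_study(small_phantom, kin, rng=np.random.default_rng(5))
    for fa, fb in zip(a.frames, b.frames):
        np.testing.assert_array_equal(fa.data, fb.data)


def test_contrast_rejects_bolus_before_first_frame(small_phantom):
    with pytest.raises(ValueError):
        make_contrast_study(
            small_phantom, KineticModel(t0_s=0.0), times=np.arange(0.0, 20.0, 2.0)
        )


# --------------------------------------------------------------------------
# dose
# --------------------------------------------------------------------------

def test_dose_peak_contralateral_and_gaussian_falloff(small_phantom):
    ph = small_phantom
    # centre on a voxel centre so grid values can be compared analytically
    centre = (48.0, 96.0, 96.0)
    dose = make_dose(ph, "R0", centre_mm=centre, sigma_mm=(16.0, 16.0, 16.0))
    ix = int(round(centre[0] / ph.image.spacing[0]))
    iy = int(round(centre[1] / ph.image.spacing[1]))
    iz = int(round(centre[2] / ph.image.spacing[2]))
    assert dose.data[ix, iy, iz] == pytest.approx(60.0)
    assert dose.data[ph.lung_left].max() < 5.0
    # 2 sigma = 32 mm = 8 voxels along x: value 60 e^-2 (outside the masked lung)
    assert dose.data[ix - 8, iy, iz] == pytest.approx(60.0 * np.exp(-2.0), abs=1e-6)


# --------------------------------------------------------------------------
# pathology sampling
# --------------------------------------------------------------------------

def _fake_assignments():
    mask = np.ones((4, 4, 4), bool)
    out = []
    for label, dose_level, fed in [
        ("MD", DoseLevel.MaxDose, FedStatus.NotFed),
        ("HLV", DoseLevel.NoDose, None),
        ("CON", DoseLevel.NoDose, FedStatus.NotFed),
        ("LDNF", DoseLevel.LowDose, FedStatus.NotFed),
    ]:
        out.append(ContourAssignment(
            label=label, roi=ROIMask(mask=mask, label=label), dose_level=dose_level,
            fed=fed,
        ))
    return out


def test_null_pathology_model_gives_no_findings():
    tables = make_pathology(
        _fake_assignments(), PathologyEffectModel(scale=0.0), n_subjects=3, seed=1
    )
    assert set(tables["collagen"].grade_label) == {"no significant"}
    assert tables["diagnoses"].empty


def test_pathology_same_seed_identical():
    a = make_pathology(_fake_assignments(), n_subjects=5, seed=9,
                       change_classes={"MD": "Decline", "HLV": "Decline"})
    b = make_pathology(_fake_assignments(), n_subjects=5, seed=9,
                       change_classes={"MD": "Decline", "HLV": "Decline"})
    assert a["collagen"].equals(b["collagen"])
    assert a["diagnoses"].equals(b["diagnoses"])


def test_pathology_dose_monotonicity_monte_carlo():
    from lungfx.concordance import parse_collagen_grade

    tables = make_pathology(
        _fake_assignments(), n_subjects=300, seed=4,
        change_classes={"MD": "Decline", "HLV": "Decline"},
    )
    coll = tables["collagen"]
    coll["grade"] = [parse_collagen_grade(g).value for g in coll.grade_label]
    means = coll.groupby("contour")["grade"].mean()
    assert means["MD"] > means["CON"]
    assert means["MD"] > means["LDNF"] > means["CON"]
    assert (coll[coll.contour == "CON"].grade == 0).all()
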