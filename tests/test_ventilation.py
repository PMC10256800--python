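"""Jacobian, LER-N, effort correction and classification contracts."""

import numpy as np
import pytest

from lungfx.core_io import ImageVolume, ROIMask
from lungfx.roi_dose import sphere_mask
from lungfx.synthetic import (
    ExpansionModel,
    build_expansion_target,
    make_breathing_series,
)
from lungfx.ventilation import (
    ChangeClass,
    DisplacementField,
    JacobianMap,
    PhaseSeries4D,
    VentilationClass,
    VentilationMap,
    classify_change,
    classify_ventilation,
    effort_correct,
    jacobian_map,
    ler_n,
    register_to_exhale,
    roi_change_ratio,
    roi_ventilation,
    warp_by_field,
)


def _field_from_function(shape, spacing, fn):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    vec = np.stack(fn(X, Y, Z), axis=-1)
    return DisplacementField(vectors=vec, spacing=spacing)


def _vmap(values, spacing=(2.0, 2.0, 2.0)):
    return VentilationMap(volume=ImageVolume(data=values, spacing=spacing))


# --------------------------------------------------------------------------
# jacobian_map
# --------------------------------------------------------------------------

def test_jacobian_of_zero_field_is_one():
    field = _field_from_function((8, 8, 8), (2, 2, 2), lambda x, y, z: (0 * x, 0 * y, 0 * z))
    np.testing.assert_allclose(jacobian_map(field).data, 1.0, atol=1e-12)


def test_jacobian_of_uniform_expansion_matches_affine_determinant():
    s = 0.1  # u = s*x -> J = (1+s)^3
    field = _field_from_function((10, 10, 10), (2, 2, 2), lambda x, y, z: (s * x, s * y, s * z))
    inner = jacobian_map(field).data[1:-1, 1:-1, 1:-1]
    np.testing.assert_allclose(inner, 1.1**3, atol=1e-6)


def test_jacobian_of_diagonal_gradient_field():
    a, b = 0.05, 0.02
    field = _field_from_function((10, 10, 10), (2, 2, 2), lambda x, y, z: (a * x, b * y, 0 * z))
    inner = jacobian_map(field).data[1:-1, 1:-1, 1:-1]
    np.testing.assert_allclose(inner, 1.05 * 1.02, atol=1e-6)


def test_jacobian_of_smooth_sinusoidal_field_within_one_percent():
    # u_x = A sin(kx): J = 1 + A k cos(kx); 2 mm spacing
    shape, spacing = (40, 8, 8), (2.0, 2.0, 2.0)
    A, k = 2.0, 2 * np.pi / 80.0
    field = _field_from_function(
        shape, spacing, lambda x, y, z: (A * np.sin(k * x), 0 * y, 0 * z)
    )
    ax = np.arange(shape[0]) * spacing[0]
    analytic = 1.0 + A * k * np.cos(k * ax)
    numeric = jacobian_map(field).data[:, 4, 4]
    rel = np.abs(numeric[1:-1] - analytic[1:-1]) / analytic[1:-1]
    assert rel.max() < 0.01


def test_jacobian_needs_three_voxels_per_axis():
    field = DisplacementField(vectors=np.zeros((2, 8, 8, 3)), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        jacobian_map(field)


# --------------------------------------------------------------------------
# ler_n
# --------------------------------------------------------------------------

def _jmap(value, shape=(4, 4, 4)):
    return JacobianMap(volume=ImageVolume(data=np.full(shape, float(value))))


def test_lern_single_phase_two_point_cycle():
    out = ler_n([_jmap(1.331)])
    np.testing.assert_allclose(out.data, 1.331)


def test_lern_static_lung_is_one():
    out = ler_n([_jmap(1.0), _jmap(1.0)])
    np.testing.assert_allclose(out.data, 1.0)


def test_lern_max_over_min_including_exhale_reference():
    # brute-force oracle over {1} U {J_k}: max/min of {1, 1.2, 0.95, 1.05}
    vals = [1.2, 0.95, 1.05]
    expected = max(vals + [1.0]) / min(vals + [1.0])
    out = ler_n([_jmap(v) for v in vals])
    np.testing.assert_allclose(out.data, expected, rtol=1e-12)
    assert expected == pytest.approx(1.2 / 0.95)


def test_lern_permutation_invariant_and_monotone(rng):
    shape = (5, 5, 5)
    maps = [
        JacobianMap(volume=ImageVolume(data=rng.uniform(0.8, 1.4, shape)))
        for _ in range(4)
    ]
    base = ler_n(maps).data
    perm = ler_n([maps[2], maps[0], maps[3], maps[1]]).data
    np.testing.assert_allclose(base, perm)
    extra = JacobianMap(volume=ImageVolume(data=rng.uniform(0.8, 1.4, shape)))
    grown = ler_n(maps + [extra]).data
    assert np.all(grown >= base - 1e-12)
    assert np.all(base >= 1.0)


def test_lern_flags_nonpositive_jacobian_voxels():
    bad = np.ones((4, 4, 4))
    bad[1, 2, 3] = -0.2
    out = ler_n([JacobianMap(volume=ImageVolume(data=bad))])
    assert not out.valid[1, 2, 3]
    assert out.valid.sum() == 63
    roi = ROIMask(mask=np.ones((4, 4, 4), bool), label="MD")
    stats = roi_ventilation(out, roi)
    assert stats["n_valid"] == 63


# --------------------------------------------------------------------------
# effort correction
# --------------------------------------------------------------------------

def test_effort_correction_rules():
    lung = ROIMask(mask=np.ones((4, 4, 4), bool), label="parenchyma-bin")
    vmap = _vmap(np.full((4, 4, 4), 1.10))
    same = effort_correct(vmap, lung, measured_tv=1.0, reference_tv=1.0)
    np.testing.assert_allclose(same.data, 1.10)
    half = effort_correct(vmap, lung, measured_tv=0.5, reference_tv=1.0)
    np.testing.assert_allclose(half.data, 1.20)
    assert half.effort_corrected
    static = effort_correct(_vmap(np.ones((4, 4, 4))), lung, 0.25, 1.0)
    np.testing.assert_allclose(static.data, 1.0)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "value,expected",
    [
        (1.25, VentilationClass.High),    # printed HHV range 1.25-1.48
        (1.02, VentilationClass.Low),     # printed LLV range 1.02-1.1
        (1.15, VentilationClass.Moderate),
        (1.2, VentilationClass.High),     # inclusive threshold
        (1.1, VentilationClass.Low),      # inclusive threshold
    ],
)
def test_classify_ventilation_thresholds(value, expected):
    assert classify_ventilation(value) == expected


def test_classify_ventilation_rejects_nonfinite():
    with pytest.raises(ValueError):
        classify_ventilation(float("nan"))


@pytest.mark.parametrize(
    "pre,post,expected_class,expected_ratio",
    [
        (1.0, 0.88, ChangeClass.Decline, 0.88),   # printed HLV mean
        (1.0, 0.95, ChangeClass.Stable, 0.95),    # printed MD outlier subject
        (1.3, 1.3, ChangeClass.Stable, 1.0),
        (1.0, 0.94, ChangeClass.Stable, 0.94),    # strict boundary
        (1.0, 1.06, ChangeClass.Stable, 1.06),    # strict boundary
        (1.0, 1.07, ChangeClass.Increase, 1.07),
    ],
)
def test_classify_change_strict_thresholds(pre, post, expected_class, expected_ratio):
    cls, ratio = classify_change(pre, post)
    assert cls == expected_class
    assert ratio == pytest.approx(expected_ratio)


def test_classify_change_rejects_nonpositive_pre():
    with pytest.raises(ValueError):
        classify_change(0.0, 1.0)


def test_roi_ventilation_statistics():
    values = np.ones((4, 4, 4))
    values[0, 0, 0] = 1.2
    vmap = _vmap(values)
    uniform_roi = ROIMask(mask=values == 1.0, label="CON")
    stats = roi_ventilation(_vmap(np.full((4, 4, 4), 1.2)), uniform_roi)
    assert stats["mean"] == pytest.approx(1.2)
    assert stats["sd"] == pytest.approx(0.0, abs=1e-12)
    two = np.zeros((4, 4, 4), bool)
    two[0, 0, 0] = two[1, 0, 0] = True
    values2 = np.ones((4, 4, 4))
    values2[1, 0, 0] = 1.2
    assert roi_ventilation(_vmap(values2), ROIMask(mask=two, label="MD"))["mean"] == pytest.approx(1.1)


# --------------------------------------------------------------------------
# registration and parameter recovery
# --------------------------------------------------------------------------

def test_register_bypass_mode_passes_fields_through(small_phantom):
    ref = small_phantom.image
    series = PhaseSeries4D(
        phases=[ref, ref.like(ref.data.copy(), frame_label="p1")], exhale_index=0
    )
    field = DisplacementField(
        vectors=np.zeros(ref.shape + (3,)), spacing=ref.spacing, phase_label="p1"
    )
    out = register_to_exhale(series, fields=[field])
    assert out[0] is field
    with pytest.raises(ValueError):
        register_to_exhale(series, fields=[field, field])


def test_warp_by_true_field_reproduces_exhale(small_phantom):
    model = ExpansionModel()
    target = build_expansion_target(small_phantom, model, [])
    study = make_breathing_series(small_phantom, target, n_phases=2, model=model)
    warped = warp_by_field(study.series.phases[1], study.true_fields[0])
    from scipy.ndimage import binary_dilation, binary_erosion

    # interpolation-limited agreement in smooth parenchyma; the lung boundary
    # and vessel edges carry ~800 HU steps where sub-voxel mismatch is intrinsic
    interior = binary_erosion(small_phantom.lungs, iterations=3)
    smooth = interior & ~binary_dilation(small_phantom.vessel_mask, iterations=2)
    err = np.abs(warped.data - study.series.exhale.data)
    assert np.mean(err[smooth]) < 5.0
    assert np.median(err[interior]) < 2.0


def test_decline_region_recovery_dice(small_phantom):
    """A 12% expansion reduction in a known region is recovered voxel-wise."""
    model = ExpansionModel(edge_sigma_mm=1.0, region_radius_mm=16.0)
    centre = tuple(np.asarray(small_phantom.spec.lung_centres_mm[0]) + [0, 0, 20])
    pre_t = build_expansion_target(small_phantom, model, [(centre, 1.20)])
    post_t = build_expansion_target(small_phantom, model, [(centre, 1.20 * 0.88)])
    pre_map = ler_n([jacobian_map(f) for f in make_breathing_series(
        small_phantom, pre_t, n_phases=2, model=model).true_fields])
    post_map = ler_n([jacobian_map(f) for f in make_breathing_series(
        small_phantom, post_t, n_phases=2, model=model).true_fields])
    ratio = post_map.data / pre_map.data
    lungs = small_phantom.lungs
    predicted = (ratio < 0.94) & lungs
    truth = sphere_mask(small_phantom.image, centre, model.region_radius_mm) & lungs
    dice = 2.0 * np.sum(predicted & truth) / (predicted.sum() + truth.sum())
    assert dice >= 0.95


def test_roi_change_ratio_methods_agree_on_uniform_change(small_phantom):
    lungs = small_phantom.lung_right
    roi = ROIMask(mask=lungs, label="parenchyma-bin")
    pre = _vmap(np.full(lungs.shape, 1.2), spacing=small_phantom.image.spacing)
    post = _vmap(np.full(lungs.shape, 1.1), spacing=small_phantom.image.spacing)
    cls1, r1 = roi_change_ratio(pre, post, roi, method="ratio_of_means")
    cls2, r2 = roi_change_ratio(pre, post, roi, method="mean_of_ratios")
    assert r1 == pytest.approx(r2)
    assert cls1 == cls2 == ChangeClass.Decline
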