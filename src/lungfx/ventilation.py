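"""Jacobian-based CT ventilation (LER-N) maps and their classification.

The local expansion ratio over N breathing phases (LER-N) estimates regional
ventilation from a respiratory-phase-resolved CT series.  Every phase is
registered to the end-exhale frame; the Jacobian determinant of each
registration gives the local volume-change factor of that phase relative to
exhale.  Per voxel, LER-N is the ratio of the largest to the smallest
expansion over the breathing cycle, with the exhale reference itself (J = 1)
included in the set, so the map is >= 1 by construction and captures regions
that expand out-of-phase from the bulk of the lung.  Typical lung values fall
in [1, 1.6].

Classification thresholds follow the operative study rules: a voxel or region
is 'High' ventilation when LER-N >= 1.2 and 'Low' when LER-N <= 1.1; a
pre-to-post treatment ratio LER-N_post / LER-N_pre < 0.94 is ventilation
decline (at least a 6% reduction, a conservative repeatability-based bound)
and a ratio > 1.06 is ventilation increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import SimpleITK as sitk

from .core_io import (
    EmptyROIError,
    ImageVolume,
    MetadataError,
    ROIMask,
    get_logger,
)

__all__ = [
    "HIGH_VENTILATION_MIN",
    "LOW_VENTILATION_MAX",
    "DECLINE_MAX_RATIO",
    "INCREASE_MIN_RATIO",
    "PhaseSeries4D",
    "DisplacementField",
    "JacobianMap",
    "VentilationMap",
    "VentilationClass",
    "ChangeClass",
    "RegistrationConfig",
    "register_to_exhale",
    "warp_by_field",
    "jacobian_map",
    "ler_n",
    "effort_correct",
    "classify_ventilation",
    "ventilation_class_map",
    "classify_change",
    "roi_ventilation",
    "roi_change_ratio",
]

log = get_logger("ventilation")

HIGH_VENTILATION_MIN = 1.2   # 'High' when LER-N >= 1.2
LOW_VENTILATION_MAX = 1.1    # 'Low'  when LER-N <= 1.1
DECLINE_MAX_RATIO = 0.94     # decline when post/pre < 0.94 (strict)
INCREASE_MIN_RATIO = 1.06    # increase when post/pre > 1.06 (strict)


class VentilationClass(Enum):
    Low = 0
    Moderate = 1
    High = 2


class ChangeClass(Enum):
    Decline = "Decline"
    Stable = "Stable"
    Increase = "Increase"


@dataclass
class PhaseSeries4D:
    """Ordered breathing-phase volumes with ventilation bookkeeping.

    The study conditions this emulates: mechanical ventilation at a tidal
    volume of 1 L and 15 breaths/min.
    """

    phases: list[ImageVolume]
    exhale_index: int
    tidal_volume: float = 1.0      # L
    respiratory_rate: float = 15.0  # breaths/min

    def __post_init__(self) -> None:
        if len(self.phases) < 2:
            raise ValueError("a 4D series needs >= 2 phases")
        if not 0 <= self.exhale_index < len(self.phases):
            raise ValueError("exhale_index out of range")
        if self.tidal_volume <= 0:
            raise ValueError("tidal volume must be positive")
        ref = self.phases[self.exhale_index]
        for ph in self.phases:
            if not ph.congruent_with(ref):
                raise MetadataError("all phases must be grid-congruent")

    @property
    def exhale(self) -> ImageVolume:
        return self.phases[self.exhale_index]

    @property
    def n_phases(self) -> int:
        return len(self.phases)


@dataclass
class DisplacementField:
    """Physical displacement (mm) mapping exhale-frame points to a phase frame.

    ``vectors[x, y, z, :]`` is the displacement of the exhale-frame voxel at
    that index; the corresponding anatomy in the phase frame sits at
    ``position + vectors``.  Grid geometry is that of the exhale phase.
    """

    vectors: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_label: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise MetadataError("spacings must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]


@dataclass
class JacobianMap:
    """Per-voxel Jacobian determinant of one phase registration."""

    volume: ImageVolume
    phase_label: str = ""

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    def positive_fraction(self, lung: ROIMask | None = None) -> float:
        """Fraction of (lung) voxels with physically plausible J > 0."""
        d = self.data if lung is None else self.data[lung.mask]
        return float(np.mean(d > 0))


@dataclass
class VentilationMap:
    """Voxel-wise LER-N with a validity mask for non-physical voxels."""

    volume: ImageVolume
    valid: np.ndarray = None
    effort_corrected: bool = False
    tidal_volume_reference: float = 1.0

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.volume.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.volume.shape:
            raise MetadataError("validity mask must match the map grid")
        vals = self.volume.data[self.valid]
        if vals.size and vals.min() < 1.0 - 1e-9:
            raise ValueError("LER-N is >= 1 at every valid voxel by construction")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


# --------------------------------------------------------------------------
# Registration
# --------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    """B-spline deformable registration settings.

    Defaults: 3-level multi-resolution image pyramid, mean-squared-error
    similarity, control-point spacing of 8 voxels, deterministic full
    sampling with an L-BFGS-B optimizer.
    """

    control_point_spacing_voxels: float = 8.0
    pyramid_levels: int = 3
    metric: str = "mse"  # {"mse", "correlation"}
    max_iterations: int = 30
    convergence_tolerance: float = 1e-5
    sampling_fraction: float = 1.0  # < 1: regular sparse sampling, seeded
    sampling_seed: int = 121212

    def __post_init__(self) -> None:
        if self.metric not in ("mse", "correlation"):
            raise ValueError("metric must be 'mse' or 'correlation'")
        if self.pyramid_levels < 1:
            raise ValueError("need >= 1 pyramid level")


def _register_pair(
    fixed: ImageVolume, moving: ImageVolume, config: RegistrationConfig
) -> np.ndarray:
    """Register ``moving`` onto ``fixed``; return displacement vectors (mm)."""
    f_img = fixed.to_sitk()
    m_img = moving.to_sitk()

    mesh = [
        max(2, int(round(n / config.control_point_spacing_voxels)))
        for n in fixed.shape
    ]
    tx = sitk.BSplineTransformInitializer(f_img, mesh, order=3)

    reg = sitk.ImageRegistrationMethod()
    if config.metric == "mse":
        reg.SetMetricAsMeanSquares()
    else:
        reg.SetMetricAsCorrelation()
    if config.sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling
    else:
        # regular sparse sampling with a fixed seed keeps runs deterministic
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(config.sampling_fraction, config.sampling_seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=config.convergence_tolerance,
        numberOfIterations=config.max_iterations,
    )
    reg.SetInitialTransform(tx, inPlace=True)
    shrink = [2 ** (config.pyramid_levels - 1 - k) for k in range(config.pyramid_levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([float(s) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

    try:
        final = reg.Execute(f_img, m_img)
    except RuntimeError as exc:
        # Non-convergence is a warning, not a hard failure.
        log.warning("registration did not converge cleanly: %s", exc)
        final = tx

    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(f_img)
    disp = filt.Execute(final)
    vec = sitk.GetArrayFromImage(disp)  # (z, y, x, 3), components already (x, y, z)
    return np.ascontiguousarray(np.transpose(vec, (2, 1, 0, 3)))


def register_to_exhale(
    series: PhaseSeries4D,
    config: RegistrationConfig | None = None,
    fields: list[DisplacementField] | None = None,
) -> list[DisplacementField]:
    """Deformably register every non-exhale phase to the end-exhale phase.

    Returns one :class:`DisplacementField` per non-exhale phase, in phase
    order.  In bypass mode (``fields`` supplied, e.g. ground-truth fields
    from a synthetic study) the provided fields are returned unchanged; this
    keeps the registration backend pluggable and lets the downstream pipeline
    be tested against analytic deformations.
    """
    if fields is not None:
        expected = series.n_phases - 1
        if len(fields) != expected:
            raise ValueError(
                f"bypass mode expects {expected} fields, got {len(fields)}"
            )
        return list(fields)
    config = config or RegistrationConfig()
    exhale = series.exhale
    out: list[DisplacementField] = []
    for k, phase in enumerate(series.phases):
        if k == series.exhale_index:
            continue
        log.info("registering phase %s to exhale", phase.frame_label or k)
        vec = _register_pair(exhale, phase, config)
        out.append(
            DisplacementField(
                vectors=vec,
                spacing=exhale.spacing,
                origin=exhale.origin,
                phase_label=phase.frame_label or str(k),
            )
        )
    return out


def warp_by_field(volume: ImageVolume, field: DisplacementField) -> ImageVolume:
    """Pull ``volume`` back through ``field``: out(x) = volume(x + u(x)).

    Warping a phase volume by its exhale-to-phase field reproduces the
    exhale volume (the registration contract).
    """
    from scipy.ndimage import map_coordinates

    if field.grid_shape != volume.shape:
        raise MetadataError("field grid must match the volume grid")
    idx = np.meshgrid(*[np.arange(n) for n in volume.shape], indexing="ij")
    coords = [
        idx[i] + field.vectors[..., i] / volume.spacing[i] for i in range(3)
    ]
    warped = map_coordinates(
        volume.data, coords, order=1, mode="constant", cval=float(volume.data.min())
    )
    return volume.like(warped, frame_label=f"warped-{field.phase_label}")


# --------------------------------------------------------------------------
# Jacobians and LER-N
# --------------------------------------------------------------------------

def jacobian_map(field: DisplacementField, phantom_like: ImageVolume | None = None) -> JacobianMap:
    """Jacobian determinant J = det(I + grad u) of a displacement field.

    The gradient is taken in physical units (mm) by central differences,
    one-sided at the grid boundary.  J > 1 marks local expansion relative to
    the exhale frame.
    """
    if any(n < 3 for n in field.grid_shape):
        raise ValueError("jacobian gradient needs >= 3 voxels per axis")
    u = field.vectors
    # D[i][j] = d u_i / d x_j
    D = [
        np.gradient(u[..., i], *field.spacing, axis=(0, 1, 2), edge_order=1)
        for i in range(3)
    ]
    a = [[D[i][j] + (1.0 if i == j else 0.0) for j in range(3)] for i in range(3)]
    det = (
        a[0][0] * (a[1][1] * a[2][2] - a[1][2] * a[2][1])
        - a[0][1] * (a[1][0] * a[2][2] - a[1][2] * a[2][0])
        + a[0][2] * (a[1][0] * a[2][1] - a[1][1] * a[2][0])
    )
    vol = ImageVolume(
        data=det,
        spacing=field.spacing,
        origin=field.origin,
        frame_label=field.phase_label,
    )
    return JacobianMap(volume=vol, phase_label=field.phase_label)


def ler_n(jacobians: list[JacobianMap]) -> VentilationMap:
    """Combine per-phase Jacobian maps into a voxel-wise LER-N map.

    Per voxel, over the set {1} U {J_k for all phases k} (the constant 1 is
    the exhale reference), LER-N = max / min.  The result is >= 1 everywhere,
    invariant to phase ordering, and monotone: adding a phase can never
    decrease it.  Voxels where any J_k <= 0 are non-physical; they are
    flagged invalid (value forced to 1) and excluded from ROI statistics.
    """
    if not jacobians:
        raise ValueError("need >= 1 Jacobian map")
    ref = jacobians[0].volume
    for jm in jacobians[1:]:
        if not jm.volume.congruent_with(ref):
            raise MetadataError("Jacobian maps must be grid-congruent")
    stack = np.stack([jm.data for jm in jacobians] + [np.ones(ref.shape)])
    valid = np.all(stack > 0, axis=0)
    hi = stack.max(axis=0)
    lo = np.where(valid, stack.min(axis=0), 1.0)
    values = np.where(valid, hi / np.where(lo > 0, lo, 1.0), 1.0)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("%d voxels with non-positive Jacobian flagged invalid", n_bad)
    vol = ImageVolume(data=values, spacing=ref.spacing, origin=ref.origin,
                      frame_label="LER-N")
    return VentilationMap(volume=vol, valid=valid)


def effort_correct(
    vmap: VentilationMap,
    lung: ROIMask,
    measured_tv: float,
    reference_tv: float = 1.0,
) -> VentilationMap:
    """Tidal-volume effort correction of a ventilation map.

    Sessions acquired at different breathing efforts are made comparable by
    rescaling the voxel excess expansion (LER-N - 1) with the single global
    factor reference_tv / measured_tv, so the lung-summed volume change
    implied by the corrected map equals the one implied at the reference
    tidal volume.  Output is clipped below at 1.
    """
    if measured_tv <= 0 or reference_tv <= 0:
        raise ValueError("tidal volumes must be positive")
    lung.check_congruent(vmap.volume)
    factor = reference_tv / measured_tv
    corrected = np.maximum(1.0, 1.0 + (vmap.data - 1.0) * factor)
    vol = vmap.volume.like(corrected)
    return VentilationMap(
        volume=vol,
        valid=vmap.valid.copy(),
        effort_corrected=True,
        tidal_volume_reference=reference_tv,
    )


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_ventilation(value: float) -> VentilationClass:
    """High when LER-N >= 1.2, Low when <= 1.1, Moderate in between."""
    if not math.isfinite(value):
        raise ValueError("LER-N value must be finite")
    if value < 0:
        raise ValueError("LER-N value must be >= 0")
    if value >= HIGH_VENTILATION_MIN:
        return VentilationClass.High
    if value <= LOW_VENTILATION_MAX:
        return VentilationClass.Low
    return VentilationClass.Moderate


def ventilation_class_map(values: np.ndarray) -> np.ndarray:
    """Vectorised ventilation classes, coded by VentilationClass.value."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("LER-N values must be finite")
    out = np.full(values.shape, VentilationClass.Moderate.value, dtype=np.int8)
    out[values >= HIGH_VENTILATION_MIN] = VentilationClass.High.value
    out[values <= LOW_VENTILATION_MAX] = VentilationClass.Low.value
    return out


def classify_change(pre_value: float, post_value: float) -> tuple[ChangeClass, float]:
    """Classify pre-to-post ventilation change from the LER-N ratio.

    Strict thresholds as printed: ratio < 0.94 is Decline, ratio > 1.06 is
    Increase; a ratio of exactly 0.94 or 1.06 is Stable.
    """
    if not (math.isfinite(pre_value) and math.isfinite(post_value)):
        raise ValueError("LER-N values must be finite")
    if pre_value <= 0:
        raise ValueError("pre-treatment LER-N must be positive")
    ratio = post_value / pre_value
    if ratio < DECLINE_MAX_RATIO:
        return ChangeClass.Decline, ratio
    if ratio > INCREASE_MIN_RATIO:
        return ChangeClass.Increase, ratio
    return ChangeClass.Stable, ratio


def roi_ventilation(vmap: VentilationMap, roi: ROIMask) -> dict:
    """Mean / sd / count of valid LER-N voxels inside an ROI."""
    roi.check_congruent(vmap.volume)
    sel = roi.mask & vmap.valid
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError(f"ROI {roi.label!r} has no valid voxels")
    vals = vmap.data[sel]
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
            "n_valid": n}


def roi_change_ratio(
    pre: VentilationMap,
    post: VentilationMap,
    roi: ROIMask,
    method: str = "ratio_of_means",
) -> tuple[ChangeClass, float]:
    """Per-contour pre-to-post change ratio and its class.

    Default is the ratio of ROI means (robust to voxel-level registration
    noise); ``method="mean_of_ratios"`` averages voxel-wise post/pre ratios
    instead so figures are reproducible either way.
    """
    roi.check_congruent(pre.volume)
    roi.check_congruent(post.volume)
    if method == "ratio_of_means":
        m_pre = roi_ventilation(pre, roi)["mean"]
        m_post = roi_ventilation(post, roi)["mean"]
        return classify_change(m_pre, m_post)
    if method == "mean_of_ratios":
        sel = roi.mask & pre.valid & post.valid
        if not sel.any():
            raise EmptyROIError(f"ROI {roi.label!r} has no valid voxels")
        ratio = float(np.mean(post.data[sel] / pre.data[sel]))
        cls, _ = classify_change(1.0, ratio)
        return cls, ratio
    raise ValueError("method must be 'ratio_of_means' or 'mean_of_ratios'")
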