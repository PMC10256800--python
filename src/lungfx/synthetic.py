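"""Synthetic 4D study generator and packaged study tables.

Everything the pipeline consumes can be generated here with seeded
reproducibility: a digital thorax phantom (two lung ellipsoids, an embedded
bifurcating vessel tree, air/parenchyma/vessel/body HU), breathing-phase
series whose displacement fields carry closed-form Jacobians, dynamic
contrast frame series driven by gamma-variate bolus kinetics, an SBRT-like
60 Gy Gaussian dose distribution honouring the contralateral < 5 Gy
constraint, and ordinal pathology outcomes statistically coupled to dose,
fed status and ventilation change.

Every generator is a pure function of (spec, seed).  The breathing-series
construction ships its own analytic Jacobian: displacement is taken along a
single axis, u_z(x, y, z) = integral over z of (T - 1), so the continuum
Jacobian determinant equals the target expansion field T exactly (only the
diagonal dz term enters the determinant), and phase fields scale u by a
cosine breathing waveform that is 0 at exhale and 1 at peak inhale.

The module also packages the study's transcribed per-subject findings
(collagen grades, diagnoses, ventilation change classes) as delimited
tables with checksums; their schema matches the synthetic outputs so every
downstream stage runs unchanged on either source.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter, map_coordinates

from .core_io import CT_AIR_HU, DoseGrid, ImageVolume, ROIMask, get_logger
from .roi_dose import VesselTree, sphere_mask
from .ventilation import DisplacementField, JacobianMap, PhaseSeries4D, VentilationMap
from .perfusion import ContrastSeries

__all__ = [
    "PhantomSpec",
    "LungPhantom",
    "ExpansionModel",
    "BreathingStudy",
    "KineticModel",
    "PathologyEffectModel",
    "make_lung_phantom",
    "make_breathing_series",
    "make_contrast_study",
    "make_dose",
    "make_pathology",
    "load_study_fixture",
]

log = get_logger("synthetic")

_DOMAIN_MM = 192.0  # physical extent of the phantom cube


class SpecError(ValueError):
    """Phantom or dose specification violates its own constraints."""


# --------------------------------------------------------------------------
# Phantom
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and randomness of the digital thorax phantom.

    The default grid is 96^3 at 2 mm spacing (a 192 mm cube); smaller grids
    keep the same physical geometry because spacing is derived from the
    fixed domain when not given explicitly.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] | None = None
    lung_centres_mm: tuple = ((58.0, 96.0, 96.0), (134.0, 96.0, 96.0))
    lung_semiaxes_mm: tuple[float, float, float] = (32.0, 42.0, 62.0)
    vessel_depth: int = 5
    root_radius_mm: float = 4.0
    parenchyma_hu: float = -750.0
    vessel_hu: float = 50.0
    body_hu: float = 0.0
    texture_sd_hu: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing is None:
            self.spacing = tuple(_DOMAIN_MM / n for n in self.shape)
        c0, c1 = (np.asarray(c) for c in self.lung_centres_mm)
        if np.linalg.norm(c1 - c0) < 2 * self.lung_semiaxes_mm[0]:
            raise SpecError("lung ellipsoids overlap under this spec")


@dataclass
class LungPhantom:
    """Generated phantom: HU image, lung/vessel masks, embedded vessel tree."""

    image: ImageVolume
    lung_right: np.ndarray   # ipsilateral
    lung_left: np.ndarray    # contralateral
    vessel_mask: np.ndarray
    vessel_voxels: dict[str, np.ndarray]  # node id -> (n, 3) voxel indices of its segment
    tree: VesselTree
    spec: PhantomSpec

    @property
    def lungs(self) -> np.ndarray:
        return self.lung_right | self.lung_left

    @property
    def parenchyma(self) -> np.ndarray:
        return self.lungs & ~self.vessel_mask

    def lung_mask(self, side: str) -> ROIMask:
        mask = self.lung_right if side == "right" else self.lung_left
        return ROIMask(mask=mask, label="parenchyma-bin", tissue="parenchyma")


def _ellipsoid(ref: ImageVolume, centre, semi) -> np.ndarray:
    ax = ref.physical_axes()
    dx = ((ax[0] - centre[0]) / semi[0])[:, None, None]
    dy = ((ax[1] - centre[1]) / semi[1])[None, :, None]
    dz = ((ax[2] - centre[2]) / semi[2])[None, None, :]
    return dx * dx + dy * dy + dz * dz <= 1.0


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec) -> nx.DiGraph:
    """Bifurcating tree per lung, rooted at a shared main inlet.

    Branches are laid out by recursive spatial subdivision: each node owns an
    axis-aligned box of its lung, split along the longest axis between its
    two children, and sits near its box centre (pulled inside the lung
    ellipsoid, with small seeded jitter).  This fills the lung the way a
    vascular tree does and guarantees that deep branches actually travel
    away from their ancestors.
    """
    g = nx.DiGraph()
    mid = (
        0.5 * (np.asarray(spec.lung_centres_mm[0]) + np.asarray(spec.lung_centres_mm[1]))
    )
    g.add_node("ROOT", position=tuple(mid), radius=spec.root_radius_mm * 1.2)

    for side, centre in zip(("R", "L"), spec.lung_centres_mm):
        centre = np.asarray(centre, dtype=float)
        semi = np.asarray(spec.lung_semiaxes_mm, dtype=float)
        sign = 1.0 if side == "R" else -1.0
        # main vessel enters at the medial hilum
        entry = centre + np.array([sign * semi[0] * 0.7, 0.0, 0.0])
        g.add_node(side, position=tuple(entry), radius=spec.root_radius_mm)
        g.add_edge("ROOT", side)

        def place(box_lo: np.ndarray, box_hi: np.ndarray) -> np.ndarray:
            pos = 0.5 * (box_lo + box_hi) + rng.uniform(-1.5, 1.5, size=3)
            for _ in range(20):
                rel = (pos - centre) / semi
                if float(np.sum(rel * rel)) <= 0.85**2:
                    break
                pos = centre + (pos - centre) * 0.9
            return pos

        def branch(parent_id: str, box_lo, box_hi, depth: int) -> None:
            if depth >= spec.vessel_depth:
                return
            axis = int(np.argmax(box_hi - box_lo))
            mid_v = 0.5 * (box_lo[axis] + box_hi[axis])
            parent_r = g.nodes[parent_id]["radius"]
            for ci in range(2):
                lo, hi = box_lo.copy(), box_hi.copy()
                if ci == 0:
                    lo[axis] = mid_v
                else:
                    hi[axis] = mid_v
                child_id = f"{parent_id}{ci}"
                g.add_node(
                    child_id,
                    position=tuple(place(lo, hi)),
                    radius=max(parent_r * 0.78, 1.2),
                )
                g.add_edge(parent_id, child_id)
                branch(child_id, lo, hi, depth + 1)

        branch(side, centre - semi, centre + semi, 0)
    return g


def _rasterize_segment(ref: ImageVolume, p0, p1, radius_mm: float) -> np.ndarray:
    """(n, 3) voxel indices within radius of the segment p0-p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    spacing = np.asarray(ref.spacing)
    origin = np.asarray(ref.origin)
    lo = np.floor((np.minimum(p0, p1) - radius_mm - origin) / spacing).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + radius_mm - origin) / spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, ref.shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    pts = np.stack([grids[i] * spacing[i] + origin[i] for i in range(3)], axis=-1)
    seg = p1 - p0
    seg_len2 = float(np.dot(seg, seg))
    rel = pts - p0
    t = np.clip(np.tensordot(rel, seg, axes=([-1], [0])) / max(seg_len2, 1e-12), 0, 1)
    nearest = p0 + t[..., None] * seg
    d2 = np.sum((pts - nearest) ** 2, axis=-1)
    sel = d2 <= radius_mm**2
    idx = np.stack([grids[i][sel] for i in range(3)], axis=-1)
    return idx


def make_lung_phantom(spec: PhantomSpec | None = None) -> LungPhantom:
    """Digital thorax: air -1000, body 0, parenchyma ~ -750, vessels ~ 50 HU."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    ref = ImageVolume(
        data=np.zeros(spec.shape), spacing=spec.spacing, origin=(0.0, 0.0, 0.0)
    )

    body = _ellipsoid(ref, (96.0, 96.0, 96.0), (88.0, 80.0, 92.0))
    lung_r = _ellipsoid(ref, spec.lung_centres_mm[0], spec.lung_semiaxes_mm)
    lung_l = _ellipsoid(ref, spec.lung_centres_mm[1], spec.lung_semiaxes_mm)
    if (lung_r & lung_l).any():
        raise SpecError("lungs overlap under this spec")

    graph = _grow_tree(rng, spec)
    tree = VesselTree(graph, "ROOT")
    vessel_mask = np.zeros(spec.shape, dtype=bool)
    vessel_voxels: dict[str, np.ndarray] = {}
    min_raster_mm = 0.8 * max(spec.spacing)  # thin segments still get voxels
    claimed = np.zeros(spec.shape, dtype=bool)
    for parent, child in nx.bfs_edges(graph, "ROOT"):
        idx = _rasterize_segment(
            ref,
            graph.nodes[parent]["position"],
            graph.nodes[child]["position"],
            max(graph.nodes[child]["radius"], min_raster_mm),
        )
        if idx.size:
            # keep vessels inside the lungs (the mediastinal stem is not
            # imaged tissue) and make per-segment voxel sets disjoint:
            # junction voxels belong to the shallowest segment claiming them
            keep = (lung_r | lung_l)[idx[:, 0], idx[:, 1], idx[:, 2]]
            keep &= ~claimed[idx[:, 0], idx[:, 1], idx[:, 2]]
            idx = idx[keep]
        vessel_voxels[child] = idx
        if idx.size:
            claimed[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            vessel_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    hu = np.full(spec.shape, CT_AIR_HU)
    hu[body] = spec.body_hu
    lungs = lung_r | lung_l
    texture = gaussian_filter(rng.standard_normal(spec.shape), sigma=2.0)
    texture *= spec.texture_sd_hu / max(texture.std(), 1e-9)
    hu[lungs] = spec.parenchyma_hu + texture[lungs]
    hu[vessel_mask] = spec.vessel_hu

    image = ImageVolume(data=hu, spacing=spec.spacing, frame_label="phantom")
    return LungPhantom(
        image=image,
        lung_right=lung_r,
        lung_left=lung_l,
        vessel_mask=vessel_mask,
        vessel_voxels=vessel_voxels,
        tree=tree,
        spec=spec,
    )


# --------------------------------------------------------------------------
# Breathing series with closed-form Jacobians
# --------------------------------------------------------------------------

@dataclass
class ExpansionModel:
    """Regional LER-N targets of the synthetic lung at peak inhale.

    Region values sit inside the printed physiological ranges: consistently
    high regions 1.25-1.48, consistently low 1.02-1.1, declining regions
    1.2-1.27 pre falling to 1.03-1.1 post.  The max-dose vessel
    neighbourhood starts moderate (1.18) and declines by the direct-response
    ratio; background lung is moderate.
    """

    background: float = 1.15
    hhv_value: float = 1.30
    llv_value: float = 1.06
    hlv_pre: float = 1.24
    hlv_post: float = 1.07
    md_post_ratio: float = 0.90    # direct-response LER ratio at full dose
    direct_onset_gy: float = 20.0  # no direct ventilation loss below this dose
    direct_full_gy: float = 45.0   # full md_post_ratio at and above this dose
    fed_post_ratio: float = 0.96   # indirect decline around fed vessels
    region_radius_mm: float = 14.0
    edge_sigma_mm: float = 3.0
    texture_sd: float = 0.0
    subject_sd: float = 0.004
    fed_subject_sd: float = 0.015  # indirect response is subject-dependent

    def waveform(self, n_phases: int) -> np.ndarray:
        """Fraction of peak displacement per phase; 0 at exhale (phase 0)."""
        k = np.arange(n_phases)
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / n_phases))


def build_expansion_target(
    phantom: LungPhantom,
    model: ExpansionModel,
    region_values_mm: list[tuple[tuple[float, float, float], float]],
    rng: np.random.Generator | None = None,
    background_field: np.ndarray | None = None,
) -> ImageVolume:
    """Per-voxel LER-N target: background lung plus labelled spherical regions.

    Regions are blended with a smooth edge so the interior plateau keeps the
    exact prescribed value while the numeric field stays differentiable.
    ``background_field`` (e.g. a dose-coupled post-treatment field) replaces
    the constant background when given.
    """
    ref = phantom.image
    target = np.ones(ref.shape)
    lungs = phantom.lungs
    if background_field is not None:
        target[lungs] = background_field[lungs]
    else:
        target[lungs] = model.background
    for centre, value in region_values_mm:
        region = sphere_mask(ref, centre, model.region_radius_mm)
        target[region & lungs] = value
    sigma_vox = [model.edge_sigma_mm / s for s in ref.spacing]
    smooth = gaussian_filter(target, sigma=sigma_vox)
    # preserve the exact plateau value inside regions; smooth only edges
    for centre, value in region_values_mm:
        core = sphere_mask(ref, centre, model.region_radius_mm - 2 * model.edge_sigma_mm)
        smooth[core & lungs] = value
    smooth[~lungs] = 1.0
    if rng is not None and model.texture_sd > 0:
        tex = gaussian_filter(rng.standard_normal(ref.shape), sigma=2.0)
        tex *= model.texture_sd / max(tex.std(), 1e-9)
        smooth[lungs] += tex[lungs]
    return ref.like(np.maximum(smooth, 1.0), frame_label="LER-target")


def build_decline_ratio_field(
    phantom: LungPhantom,
    model: ExpansionModel,
    dose: DoseGrid,
    fed_segment_masks: dict[str, np.ndarray] | None = None,
    jitter: dict[str, float] | None = None,
) -> np.ndarray:
    """Voxel-wise post/pre LER ratio encoding the treatment response.

    Direct response: the ratio falls linearly from 1 (at ``direct_onset_gy``)
    to ``md_post_ratio`` (at ``direct_full_gy`` and above), so ventilation
    loss follows the delivered dose.  Indirect response: voxels around fed
    vessel segments (masks keyed by contour label) are additionally scaled
    by ``fed_post_ratio``, with per-subject jitter expressing the
    subject-dependence of the indirect effect.
    """
    jitter = jitter or {}
    span = max(model.direct_full_gy - model.direct_onset_gy, 1e-6)
    s = np.clip((dose.data - model.direct_onset_gy) / span, 0.0, 1.0)
    md_ratio = model.md_post_ratio * jitter.get("MD", 1.0)
    ratio = 1.0 - (1.0 - md_ratio) * s
    for lbl, mask in (fed_segment_masks or {}).items():
        ratio[mask] *= model.fed_post_ratio * jitter.get(lbl, 1.0)
    return ratio


@dataclass
class BreathingStudy:
    """A generated 4D series plus its ground truth."""

    series: PhaseSeries4D
    true_fields: list[DisplacementField]     # one per non-exhale phase, in order
    true_jacobians: list[JacobianMap]
    target: ImageVolume                      # prescribed LER-N field


def make_breathing_series(
    phantom: LungPhantom,
    target: ImageVolume,
    n_phases: int = 10,
    model: ExpansionModel | None = None,
    generate_images: bool = True,
) -> BreathingStudy:
    """Breathing-phase series whose analytic peak Jacobian equals ``target``.

    The displacement potential is integrated along z from the lung
    mid-plane, u_z = int_z (T - 1) dz, so det(I + grad u) = T exactly in the
    continuum (cross-derivatives of a z-only displacement do not enter the
    determinant).  Phase k scales u by the breathing waveform w_k in [0, 1]
    with w = 0 at end-exhale; its analytic Jacobian is 1 + w_k (T - 1).
    """
    if n_phases < 2:
        raise ValueError("need >= 2 phases")
    model = model or ExpansionModel()
    ref = phantom.image
    if not target.congruent_with(ref):
        raise ValueError("target field must live on the phantom grid")
    T = target.data
    if np.max(np.abs(T - 1.0)) > 0.6:
        log.warning("target |J-1| exceeds 0.6: outside the small-deformation regime")

    dz = ref.spacing[2]
    cum = cumulative_trapezoid(T - 1.0, dx=dz, axis=2, initial=0.0)
    zc = int(np.argwhere(phantom.lungs).mean(axis=0)[2])
    u_z = cum - cum[:, :, zc : zc + 1]

    w = model.waveform(n_phases)
    fields: list[DisplacementField] = []
    jacobians: list[JacobianMap] = []
    phases = [ref.like(ref.data.copy(), frame_label="phase-0")]
    idx = np.meshgrid(*[np.arange(n) for n in ref.shape], indexing="ij")
    for k in range(1, n_phases):
        vec = np.zeros(ref.shape + (3,))
        vec[..., 2] = w[k] * u_z
        fields.append(
            DisplacementField(
                vectors=vec, spacing=ref.spacing, origin=ref.origin,
                phase_label=f"phase-{k}",
            )
        )
        jacobians.append(
            JacobianMap(
                volume=ref.like(1.0 + w[k] * (T - 1.0), frame_label=f"phase-{k}"),
                phase_label=f"phase-{k}",
            )
        )
        if generate_images:
            # invert y = x + u(x) by fixed point (z-only displacement)
            xz = idx[2].astype(float)
            for _ in range(4):
                u_at = map_coordinates(u_z, [idx[0], idx[1], xz], order=1, mode="nearest")
                xz = idx[2] - w[k] * u_at / dz
            warped = map_coordinates(
                ref.data, [idx[0], idx[1], xz], order=1, mode="nearest"
            )
            phases.append(ref.like(warped, frame_label=f"phase-{k}"))

    if not generate_images:
        phases = [ref.like(ref.data, frame_label=f"phase-{k}") for k in range(n_phases)]
    series = PhaseSeries4D(phases=phases, exhale_index=0)
    return BreathingStudy(
        series=series, true_fields=fields, true_jacobians=jacobians, target=target
    )


# --------------------------------------------------------------------------
# Dose
# --------------------------------------------------------------------------

def make_dose(
    phantom: LungPhantom,
    target_node: str,
    prescription: float = 60.0,
    sigma_mm: tuple[float, float, float] = (16.0, 16.0, 16.0),
    contralateral_cap_gy: float = 4.5,
    centre_mm: tuple[float, float, float] | None = None,
) -> DoseGrid:
    """Anisotropic Gaussian dose centred on a vessel node, peak = prescription.

    By default the Gaussian centres on the midpoint of the target node's
    incoming segment so that segment carries the maximum mean dose.  The
    contralateral (left) lung is capped below 5 Gy by masking, matching the
    planning constraint of the emulated treatments.
    """
    if target_node not in phantom.tree.graph:
        raise KeyError(f"unknown vessel node {target_node!r}")
    if centre_mm is not None:
        centre = np.asarray(centre_mm, dtype=float)
    else:
        parent = phantom.tree.parent(target_node)
        centre = phantom.tree.position(target_node)
        if parent is not None:
            centre = 0.5 * (centre + phantom.tree.position(parent))
    ax = phantom.image.physical_axes()
    ex = ((ax[0] - centre[0]) ** 2 / (2 * sigma_mm[0] ** 2))[:, None, None]
    ey = ((ax[1] - centre[1]) ** 2 / (2 * sigma_mm[1] ** 2))[None, :, None]
    ez = ((ax[2] - centre[2]) ** 2 / (2 * sigma_mm[2] ** 2))[None, None, :]
    dose = prescription * np.exp(-(ex + ey + ez))
    dose[phantom.lung_left] = np.minimum(dose[phantom.lung_left], contralateral_cap_gy)
    contra_max = float(dose[phantom.lung_left].max())
    if contra_max >= 5.0:
        raise SpecError(
            f"contralateral lung max {contra_max:.2f} Gy violates the < 5 Gy constraint"
        )
    vol = ImageVolume(
        data=dose, spacing=phantom.image.spacing, origin=phantom.image.origin,
        frame_label="dose",
    )
    return DoseGrid(volume=vol, prescription=prescription)


def annotate_tree_doses(phantom: LungPhantom, dose: DoseGrid) -> None:
    """Attach per-node mean dose over each node's segment voxels."""
    for node in phantom.tree.node_ids:
        idx = phantom.vessel_voxels.get(node)
        if idx is None or not len(idx):
            pos = phantom.tree.position(node)
            vox = np.round(
                (pos - np.asarray(phantom.image.origin)) / np.asarray(phantom.image.spacing)
            ).astype(int)
            vox = np.clip(vox, 0, np.asarray(phantom.image.shape) - 1)
            phantom.tree.set_mean_dose(node, float(dose.data[tuple(vox)]))
        else:
            phantom.tree.set_mean_dose(
                node, float(dose.data[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
            )


# --------------------------------------------------------------------------
# Contrast kinetics
# --------------------------------------------------------------------------

@dataclass
class KineticModel:
    """Gamma-variate bolus kinetics with post-treatment effect structure.

    The bolus shape is the peak-normalised gamma variate
    gamma(t) = ((t - t0) / (alpha beta))^alpha * exp(alpha - (t - t0)/beta),
    which peaks at exactly 1 at t = t0 + alpha*beta, so the amplitude A is
    directly the peak enhancement in HU.  Parenchyma follows a scaled,
    delayed copy of the vessel curve.  Post-treatment, vessels fed by (or
    at) the maximally irradiated vessel lose a fraction of their amplitude
    (AUC scales linearly with amplitude); vessels above a dose threshold
    additionally lose peak enhancement in proportion to dose, and the
    surrounding parenchyma baseline rises by a fixed fraction of the local
    vessel peak loss.
    """

    amplitude_hu: float = 250.0
    t0_s: float = 8.0
    alpha: float = 2.0
    beta_s: float = 3.0
    parenchyma_fraction: float = 0.12
    parenchyma_delay_s: float = 3.0
    noise_sd_hu: float = 15.0
    fed_auc_multiplier: float = 0.6
    peak_loss_per_gy: float = 4.0
    dose_threshold_gy: float = 25.0
    parenchyma_vessel_slope: float = -0.6
    subject_sd: float = 0.03

    def bolus(self, t: np.ndarray, delay: float = 0.0) -> np.ndarray:
        tt = np.asarray(t, dtype=float) - self.t0_s - delay
        out = np.zeros_like(tt)
        pos = tt > 0
        s = tt[pos] / (self.alpha * self.beta_s)
        out[pos] = s**self.alpha * np.exp(self.alpha - tt[pos] / self.beta_s)
        return out

    def vessel_peak_delta(self, dose_gy: float) -> float:
        """Direct-response peak loss (HU, <= 0) at a given dose."""
        return -self.peak_loss_per_gy * max(0.0, dose_gy - self.dose_threshold_gy)


def default_timeline(n_pre: int = 4, n_total: int = 24, dt_s: float = 2.0) -> np.ndarray:
    return np.arange(n_total) * dt_s  # injection near t0 = 8 s -> 4 pre frames


def make_contrast_study(
    phantom: LungPhantom,
    kinetics: KineticModel | None = None,
    times: np.ndarray | None = None,
    post: bool = False,
    fed_nodes: set[str] | None = None,
    rng: np.random.Generator | None = None,
    dose: DoseGrid | None = None,
) -> tuple[ContrastSeries, dict[str, float]]:
    """Dynamic contrast frame series plus the true per-node effect multipliers.

    Returns ``(series, effect)`` where ``effect[node]`` is the realised
    post/pre amplitude (and hence AUC) ratio for that vessel node; all 1.0
    for a pre-treatment study.
    """
    kinetics = kinetics or KineticModel()
    times = default_timeline() if times is None else np.asarray(times, dtype=float)
    if kinetics.t0_s <= times[0]:
        raise ValueError("bolus arrival t0 must fall after the first frame")
    rng = rng or np.random.default_rng(0)
    fed_nodes = fed_nodes or set()

    ref = phantom.image
    base = ref.data.copy()

    amp = np.zeros(ref.shape)
    effect: dict[str, float] = {}
    for node, idx in phantom.vessel_voxels.items():
        if not len(idx):
            continue
        a_vox = np.full(len(idx), kinetics.amplitude_hu)
        if post:
            # direct response: peak loss follows the local voxel dose when a
            # dose grid is supplied, else the node's mean dose
            if dose is not None:
                vox_dose = dose.data[idx[:, 0], idx[:, 1], idx[:, 2]]
            else:
                vox_dose = np.full(len(idx), phantom.tree.mean_dose(node) or 0.0)
            a_vox = np.maximum(
                0.0,
                a_vox - kinetics.peak_loss_per_gy
                * np.maximum(0.0, vox_dose - kinetics.dose_threshold_gy),
            )
            if node in fed_nodes:
                a_vox *= kinetics.fed_auc_multiplier
            a_vox *= max(0.1, 1.0 + kinetics.subject_sd * rng.standard_normal())
        effect[node] = float(a_vox.mean() / kinetics.amplitude_hu)
        amp[idx[:, 0], idx[:, 1], idx[:, 2]] = a_vox

    par = phantom.parenchyma
    par_amp = np.zeros(ref.shape)
    par_amp[par] = kinetics.parenchyma_fraction * kinetics.amplitude_hu
    if post and dose is not None:
        # leakage: parenchyma baseline rises with the local vessel peak loss
        loss = kinetics.peak_loss_per_gy * np.maximum(
            0.0, dose.data - kinetics.dose_threshold_gy
        )
        base[par] += -kinetics.parenchyma_vessel_slope * loss[par]

    g_vessel = kinetics.bolus(times)
    g_par = kinetics.bolus(times, delay=kinetics.parenchyma_delay_s)
    frames = []
    for i, t in enumerate(times):
        frame = base + amp * g_vessel[i] + par_amp * g_par[i]
        if kinetics.noise_sd_hu > 0:
            frame = frame + rng.normal(0.0, kinetics.noise_sd_hu, size=ref.shape)
        frames.append(ref.like(frame, frame_label=f"frame-{i}"))
    series = ContrastSeries(frames=frames, times=times, breathhold=True)
    return series, effect


# --------------------------------------------------------------------------
# Pathology outcomes
# --------------------------------------------------------------------------

@dataclass
class PathologyEffectModel:
    """Maps (dose level, fed status, ventilation change) to collagen grades
    and diagnosis probabilities; expected grade is monotone in dose."""

    base_grade: float = 0.3
    dose_grade: dict = field(
        default_factory=lambda: {"NoDose": 0.0, "LowDose": 0.8, "MaxDose": 3.0}
    )
    fed_grade: float = 0.7
    decline_grade: float = 2.8
    grade_sd: float = 0.3
    grade_cap: float = 4.0  # no 'severe' grades, as observed
    scale: float = 1.0      # 0 disables all effects (null model)
    diagnosis_slopes: dict = field(
        default_factory=lambda: {
            "fibrosis": (0.05, 0.28),
            "inflammation": (0.10, 0.25),
            "chondrocyte_necrosis": (0.10, 0.22),
            "histiocytosis": (0.05, 0.18),
            "bronchitis": (0.0, 0.15),
        }
    )

    def expected_grade(self, dose_level: str, fed: bool, decline: bool) -> float:
        mean = self.base_grade + self.dose_grade.get(dose_level, 0.0)
        if fed:
            mean += self.fed_grade
        if decline:
            mean += self.decline_grade
        return self.scale * min(mean, self.grade_cap)


_GRADE_LABELS = {
    0.0: "no significant", 0.5: "no significant-minimal", 1.0: "minimal",
    1.5: "minimal-mild", 2.0: "mild", 2.5: "mild-moderate", 3.0: "moderate",
    3.5: "moderate-marked", 4.0: "marked", 4.5: "marked-severe", 5.0: "severe",
}


def make_pathology(
    assignments: list,
    model: PathologyEffectModel | None = None,
    n_subjects: int = 5,
    seed: int = 0,
    change_classes: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Sample collagen grades and diagnoses for simulated subjects.

    ``assignments`` is a list of :class:`~lungfx.roi_dose.ContourAssignment`;
    ``change_classes`` optionally maps (subject index, contour label) or
    contour label to a ventilation ChangeClass value used for the decline
    coupling.  Returns ``{"collagen": df, "diagnoses": df}`` with the
    packaged fixture schema.
    """
    from .roi_dose import DoseLevel, FedStatus

    model = model or PathologyEffectModel()
    rng = np.random.default_rng(seed)
    subjects = [chr(ord("A") + i) for i in range(n_subjects)]
    coll_rows, diag_rows = [], []
    for si, subject in enumerate(subjects):
        for a in assignments:
            dose_level = a.dose_level.value if a.dose_level else "NoDose"
            fed = a.fed == FedStatus.Fed
            decline = False
            if change_classes is not None:
                cc = change_classes.get((si, a.label), change_classes.get(a.label))
                decline = str(getattr(cc, "value", cc)) == "Decline"
            if a.label == "CON":
                mean = 0.0
            else:
                mean = model.expected_grade(dose_level, fed, decline)
            if mean == 0.0:
                grade = 0.0
            else:
                grade = float(
                    np.clip(
                        np.round(rng.normal(mean, model.grade_sd) * 2.0) / 2.0,
                        0.0,
                        model.grade_cap,
                    )
                )
            coll_rows.append(
                {
                    "subject": subject,
                    "contour": a.label,
                    "grade_label": _GRADE_LABELS[grade],
                    "artifact_suspect": False,
                }
            )
            for diagnosis, (p0, slope) in model.diagnosis_slopes.items():
                p = model.scale * min(1.0, p0 + slope * grade)
                if a.label == "CON":
                    p = 0.0
                if rng.random() < p:
                    strength = float(
                        np.clip(np.round(rng.normal(max(grade, 1.0), 0.5) * 2) / 2, 0.5, 4.0)
                    )
                    diag_rows.append(
                        {
                            "subject": subject,
                            "contour": a.label,
                            "diagnosis": diagnosis,
                            "strength_label": _GRADE_LABELS[strength],
                        }
                    )
    return {
        "collagen": pd.DataFrame(coll_rows),
        "diagnoses": pd.DataFrame(
            diag_rows, columns=["subject", "contour", "diagnosis", "strength_label"]
        ),
    }


# --------------------------------------------------------------------------
# Packaged study tables
# --------------------------------------------------------------------------

class PackagingError(RuntimeError):
    """A packaged fixture fails its recorded checksum."""


def _read_packaged(name: str) -> pd.DataFrame:
    source = resources.files("lungfx.data").joinpath(name)
    raw = source.read_bytes()
    manifest = json.loads(
        resources.files("lungfx.data").joinpath("checksums.json").read_text()
    )
    digest = hashlib.sha256(raw).hexdigest()
    if manifest.get(name) != digest:
        raise PackagingError(f"checksum mismatch for packaged table {name}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), encoding="utf-8")


def load_study_fixture(name: str) -> dict[str, pd.DataFrame]:
    """Load the transcribed per-subject study tables.

    ``"groupB"`` returns ``{"ventilation", "collagen", "diagnoses"}`` for
    the five fully-characterised subjects across all nine contours;
    ``"groupA"`` returns the feasibility-cohort findings plus derived
    ventilation/collagen tables (binary collagen stored as grades {0, 2} so
    the same damage rules apply).
    """
    if name == "groupB":
        return {
            "ventilation": _read_packaged("groupB_ventilation.csv"),
            "collagen": _read_packaged("groupB_collagen.csv"),
            "diagnoses": _read_packaged("groupB_diagnoses.csv"),
        }
    if name == "groupA":
        findings = _read_packaged("groupA_findings.csv")
        cells = findings.drop_duplicates(["subject", "contour"])
        ventilation = cells[["subject", "contour", "change_class"]].reset_index(drop=True)
        collagen = pd.DataFrame(
            {
                "subject": cells.subject,
                "contour": cells.contour,
                "grade_label": np.where(
                    cells.collagen_present.astype(int) == 1, "mild", "no significant"
                ),
                "artifact_suspect": False,
            }
        ).reset_index(drop=True)
        diagnoses = findings.dropna(subset=["diagnosis"])[
            ["subject", "contour", "diagnosis"]
        ].copy()
        diagnoses["strength_label"] = "mild"
        return {
            "findings": findings,
            "ventilation": ventilation,
            "collagen": collagen,
            "diagnoses": diagnoses.reset_index(drop=True),
        }
    raise ValueError("fixture name must be 'groupA' or 'groupB'")
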