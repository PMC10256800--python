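"""End-to-end synthetic study orchestration.

Runs the full pipeline the way the emulated experiment was run: build one
thorax phantom, plan a 60 Gy Gaussian dose on a vessel, derive the nine
analysis contours (max-dose, low/no-dose x fed/not-fed vessels, mirrored
contralateral control, and the three ventilation-selected parenchymal
points), then for each simulated subject generate pre- and post-treatment
breathing and contrast studies, compute LER-N ventilation maps and
time-attenuation metrics, classify per-contour change, and tabulate paired
statistics across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import paired_t_test
from .core_io import DoseGrid, ROIMask, get_logger, save_table
from .perfusion import compute_metrics, extract_curve
from .roi_dose import (
    ContourAssignment,
    DoseLevel,
    FedStatus,
    classify_dose_level,
    fed_status,
    mirror_contralateral,
    select_ventilation_points,
    sphere_mask,
)
from .synthetic import (
    ExpansionModel,
    KineticModel,
    LungPhantom,
    PathologyEffectModel,
    PhantomSpec,
    build_decline_ratio_field,
    build_expansion_target,
    make_breathing_series,
    make_contrast_study,
    make_dose,
    make_lung_phantom,
    make_pathology,
    annotate_tree_doses,
)
from .ventilation import ChangeClass, ler_n, roi_change_ratio, roi_ventilation

__all__ = ["StudyConfig", "StudyContours", "StudyResult", "build_study_contours", "run_synthetic_study"]

log = get_logger("study")


@dataclass
class StudyConfig:
    """Study conditions for the simulated cohort.

    Defaults emulate the study design: five subjects, ten breathing phases
    at 1 L tidal volume, a 60 Gy prescription, and the generator's default
    effect sizes.
    """

    n_subjects: int = 5
    n_phases: int = 10
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    expansion: ExpansionModel = field(default_factory=ExpansionModel)
    kinetics: KineticModel = field(default_factory=KineticModel)
    pathology: PathologyEffectModel = field(default_factory=PathologyEffectModel)
    dose_sigma_mm: tuple[float, float, float] = (16.0, 16.0, 16.0)
    vessel_roi_radius_mm: float = 8.0
    ventilation_point_radius_mm: float = 10.0
    generate_phase_images: bool = False


@dataclass
class StudyContours:
    """The nine analysis contours on the shared phantom geometry."""

    assignments: dict[str, ContourAssignment]
    dose: DoseGrid
    ptv: ROIMask
    md_node: str
    fed_nodes: set[str]
    vent_centres: dict[str, tuple[float, float, float]]


@dataclass
class StudyResult:
    phantom: LungPhantom
    contours: StudyContours
    ventilation_table: pd.DataFrame
    perfusion_table: pd.DataFrame
    ttest_table: pd.DataFrame
    pathology: dict[str, pd.DataFrame]

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        written = [
            save_table(self.ventilation_table, out_dir / "ventilation_roi.csv"),
            save_table(self.perfusion_table, out_dir / "perfusion_auc.csv"),
            save_table(self.ttest_table, out_dir / "auc_ttests.csv"),
            save_table(self.pathology["collagen"], out_dir / "collagen.csv"),
            save_table(self.pathology["diagnoses"], out_dir / "diagnoses.csv"),
        ]
        self.contours.dose  # dose grid kept in memory; volumes written on demand
        return written


def _vessel_roi(phantom: LungPhantom, node: str, label: str) -> ROIMask:
    idx = phantom.vessel_voxels[node]
    mask = np.zeros(phantom.image.shape, dtype=bool)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return ROIMask(mask=mask, label=label, tissue="vessel")


def _pick_node(candidates: list[str], phantom: LungPhantom) -> str | None:
    """The largest measurable vessel in a category gets contoured."""
    if not candidates:
        return None
    return sorted(
        candidates, key=lambda n: (-len(phantom.vessel_voxels[n]), n)
    )[0]


def build_study_contours(phantom: LungPhantom, config: StudyConfig) -> StudyContours:
    """Plan dose and derive the vessel and control contours on the phantom.

    The prescription targets a second-generation vessel of the right
    (ipsilateral) lung so that downstream branches span the low- and
    no-dose ranges; fed status follows the tree topology and the
    contralateral control mirrors the max-dose point.
    """
    tree = phantom.tree
    dose = make_dose(phantom, target_node="R0", sigma_mm=config.dose_sigma_mm)
    annotate_tree_doses(phantom, dose)

    md_node = tree.max_dose_node()
    fed = tree.descendants(md_node)
    right_nodes = [
        n for n in tree.node_ids
        if n.startswith("R") and n != "ROOT" and len(phantom.vessel_voxels.get(n, ())) >= 3
    ]

    ref = phantom.image
    ptv_mask = sphere_mask(ref, tree.position(md_node), 10.0)
    ptv = ROIMask(mask=ptv_mask, label="vessel-bin", tissue="vessel")

    def in_range(n, lo, hi):
        d = tree.mean_dose(n) or 0.0
        return lo <= d <= hi

    def outside_ptv(n):
        idx = phantom.vessel_voxels[n]
        return not ptv_mask[idx[:, 0], idx[:, 1], idx[:, 2]].any()

    eligible = [n for n in right_nodes if outside_ptv(n)]
    ldf = _pick_node([n for n in eligible if n in fed and in_range(n, 5, 20)], phantom)
    ndf = _pick_node([n for n in eligible if n in fed and (tree.mean_dose(n) or 0) < 5], phantom)
    not_fed = [n for n in eligible if n not in fed and n != md_node
               and md_node not in tree.descendants(n)]
    ldnf = _pick_node([n for n in not_fed if in_range(n, 5, 20)], phantom)
    ndnf = _pick_node([n for n in not_fed if (tree.mean_dose(n) or 0) < 5], phantom)
    missing = [lbl for lbl, n in
               (("LDF", ldf), ("NDF", ndf), ("LDNF", ldnf), ("NDNF", ndnf)) if n is None]
    if missing:
        raise RuntimeError(f"phantom vessel tree lacks contour categories: {missing}")
    lung_r = phantom.lung_mask("right")
    lung_l = phantom.lung_mask("left")

    assignments: dict[str, ContourAssignment] = {}
    for label, node in (("MD", md_node), ("LDF", ldf), ("NDF", ndf),
                        ("LDNF", ldnf), ("NDNF", ndnf)):
        roi = _vessel_roi(phantom, node, label)
        assignments[label] = ContourAssignment(
            label=label,
            roi=roi,
            dose_level=classify_dose_level(roi, dose, ptv),
            fed=fed_status(tree, node, md_node),
            vessel_node=node,
            centroid_mm=tuple(tree.position(node)),
        )
    con_roi = mirror_contralateral(assignments["MD"].roi, lung_r, lung_l, ref)
    assignments["CON"] = ContourAssignment(
        label="CON",
        roi=con_roi,
        dose_level=classify_dose_level(con_roi, dose, ptv),
        fed=FedStatus.NotFed,
    )

    # designed ventilation-point region centres: parenchymal spots in the
    # ipsilateral lung, clear of the contoured vessels, of each other and of
    # the high-dose region (the emulated points are distinct tissue sections)
    lc = np.asarray(config.phantom.lung_centres_mm[0])
    semi = np.asarray(config.phantom.lung_semiaxes_mm)
    vessel_coords = np.concatenate([
        np.argwhere(assignments[lbl].roi.mask)
        * np.asarray(ref.spacing) + np.asarray(ref.origin)
        for lbl in ("MD", "LDF", "NDF", "LDNF", "NDNF")
    ])
    region_r = config.expansion.region_radius_mm
    candidate_offsets = [
        (float(ox), float(oy), float(oz))
        for oz in range(-44, 45, 4)
        for oy in range(-28, 29, 4)
        for ox in range(-20, 21, 4)
    ]
    vent_centres: dict[str, tuple[float, float, float]] = {}
    for label in ("HHV", "LLV", "HLV"):
        best, best_clearance = None, -1.0
        for off in candidate_offsets:
            centre = lc + np.asarray(off)
            rel = (centre - lc) / semi
            if np.sum(rel * rel) > 0.75**2:
                continue
            if any(
                np.linalg.norm(np.asarray(c) - centre) < 2 * region_r + 4.0
                for c in vent_centres.values()
            ):
                continue
            idx = np.clip(
                np.round((centre - np.asarray(ref.origin)) / np.asarray(ref.spacing)).astype(int),
                0, np.asarray(ref.shape) - 1,
            )
            if dose.data[tuple(idx)] > 10.0:
                continue
            clearance = float(np.min(np.linalg.norm(vessel_coords - centre, axis=1)))
            if clearance > best_clearance + 1e-9:
                best, best_clearance = centre, clearance
        if best is None or best_clearance < region_r + 2.0:
            raise RuntimeError(f"no admissible centre for ventilation point {label}")
        vent_centres[label] = tuple(float(v) for v in best)
    return StudyContours(
        assignments=assignments,
        dose=dose,
        ptv=ptv,
        md_node=md_node,
        fed_nodes=set(fed),
        vent_centres=vent_centres,
    )


def _expansion_regions(contours: StudyContours, model: ExpansionModel, jitter,
                       post: bool) -> list[tuple[tuple[float, float, float], float]]:
    """Ventilation-point region values for one timepoint, with subject jitter."""
    hlv = model.hlv_post if post else model.hlv_pre
    return [
        (contours.vent_centres["HHV"], model.hhv_value * jitter["HHV"]),
        (contours.vent_centres["LLV"], model.llv_value * jitter["LLV"]),
        (contours.vent_centres["HLV"], hlv * jitter["HLV"]),
    ]


def _fed_segment_masks(phantom: LungPhantom, contours: StudyContours) -> dict[str, np.ndarray]:
    """Dilated voxel masks of the fed low/no-dose vessel segments."""
    from scipy.ndimage import binary_dilation

    masks = {}
    for lbl in ("LDF", "NDF"):
        node = contours.assignments[lbl].vessel_node
        idx = phantom.vessel_voxels[node]
        m = np.zeros(phantom.image.shape, dtype=bool)
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        masks[lbl] = binary_dilation(m, iterations=2)
    return masks


def run_synthetic_study(config: StudyConfig | None = None) -> StudyResult:
    """Simulate the cohort and run the full biomarker pipeline on it.

    Ventilation maps are computed from the generators' analytic Jacobians
    (registration bypass); the registration arm is exercised separately
    because it is the pipeline's slowest stage.  Returns all per-contour
    tables plus sampled pathology coupled to the realised change classes.
    """
    config = config or StudyConfig()
    rng_root = np.random.SeedSequence([config.seed, 7771])
    phantom = make_lung_phantom(config.phantom)
    contours = build_study_contours(phantom, config)

    vent_rows, perf_rows = [], []
    subjects = [chr(ord("A") + i) for i in range(config.n_subjects)]
    realised_changes: dict[tuple[int, str], ChangeClass] = {}
    vent_assignments = None
    for si, (subject, seq) in enumerate(zip(subjects, rng_root.spawn(config.n_subjects))):
        rng = np.random.default_rng(seq)
        jitter = {
            lbl: 1.0 + config.expansion.subject_sd * rng.standard_normal()
            for lbl in ("HHV", "LLV", "HLV", "MD")
        }
        jitter.update({
            lbl: 1.0 + config.expansion.fed_subject_sd * rng.standard_normal()
            for lbl in ("LDF", "NDF")
        })
        decline_ratio = build_decline_ratio_field(
            phantom, config.expansion, contours.dose,
            fed_segment_masks=_fed_segment_masks(phantom, contours),
            jitter=jitter,
        )
        maps = {}
        for post in (False, True):
            background = None
            if post:
                background = np.maximum(
                    1.0, 1.0 + (config.expansion.background - 1.0) * np.ones(phantom.image.shape)
                ) * decline_ratio
            target = build_expansion_target(
                phantom,
                config.expansion,
                _expansion_regions(contours, config.expansion, jitter, post),
                rng=rng,
                background_field=background,
            )
            study = make_breathing_series(
                phantom, target, n_phases=config.n_phases,
                model=config.expansion,
                generate_images=config.generate_phase_images,
            )
            maps[post] = ler_n(study.true_jacobians)

        # ventilation-selected parenchymal points (first subject defines them,
        # as in the emulated protocol where points were chosen once per subject)
        points = select_ventilation_points(
            maps[False], maps[True], phantom.lung_mask("right"),
            radius_mm=config.ventilation_point_radius_mm,
        )
        subject_assignments = dict(contours.assignments)
        for lbl, assignment in points.items():
            if assignment is not None:
                subject_assignments[lbl] = assignment
        if vent_assignments is None:
            vent_assignments = subject_assignments

        for lbl, assignment in subject_assignments.items():
            cls, ratio = roi_change_ratio(maps[False], maps[True], assignment.roi)
            pre_stats = roi_ventilation(maps[False], assignment.roi)
            post_stats = roi_ventilation(maps[True], assignment.roi)
            realised_changes[(si, lbl)] = cls
            vent_rows.append(
                {
                    "subject": subject,
                    "contour": lbl,
                    "mean_pre": pre_stats["mean"],
                    "mean_post": post_stats["mean"],
                    "ratio": ratio,
                    "change_class": cls.value,
                }
            )

        # perfusion: pre/post contrast series, AUC per vessel contour
        pre_series, _ = make_contrast_study(
            phantom, config.kinetics, post=False, rng=np.random.default_rng(seq.spawn(1)[0])
        )
        post_series, effects = make_contrast_study(
            phantom, config.kinetics, post=True,
            fed_nodes=contours.fed_nodes | {contours.md_node},
            rng=np.random.default_rng(seq.spawn(2)[1]),
            dose=contours.dose,
        )
        for lbl in ("MD", "LDF", "NDF", "LDNF", "NDNF", "CON"):
            a = subject_assignments[lbl]
            roi = a.roi
            m_pre = compute_metrics(extract_curve(pre_series, roi, n_precontrast=4))
            m_post = compute_metrics(extract_curve(post_series, roi, n_precontrast=4))
            perf_rows.append(
                {
                    "subject": subject,
                    "contour": lbl,
                    "auc_pre": m_pre.auc,
                    "auc_post": m_post.auc,
                    "auc_ratio": m_post.auc / m_pre.auc if m_pre.auc else np.nan,
                    "peak_pre": m_pre.peak_enhancement,
                    "peak_post": m_post.peak_enhancement,
                    "true_effect": effects.get(a.vessel_node, np.nan),
                }
            )

    ventilation_table = pd.DataFrame(vent_rows)
    perfusion_table = pd.DataFrame(perf_rows)

    t_rows = []
    for lbl, grp in perfusion_table.groupby("contour"):
        res = paired_t_test(grp.auc_pre.to_numpy(), grp.auc_post.to_numpy())
        t_rows.append(
            {
                "contour": lbl,
                "t": res.t,
                "p_two_tailed": res.p_two_tailed,
                "n": res.n,
                "mean_auc_ratio": float(grp.auc_ratio.mean()),
            }
        )
    ttest_table = pd.DataFrame(t_rows).sort_values("contour").reset_index(drop=True)

    pathology = make_pathology(
        list(vent_assignments.values()),
        model=config.pathology,
        n_subjects=config.n_subjects,
        seed=int(rng_root.spawn(1)[0].generate_state(1)[0] % (2**31)),
        change_classes=realised_changes,
    )
    return StudyResult(
        phantom=phantom,
        contours=contours,
        ventilation_table=ventilation_table,
        perfusion_table=perfusion_table,
        ttest_table=ttest_table,
        pathology=pathology,
    )
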