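"""Construction and classification of the nine analysis contours.

The study evaluates regional radiation response at vessel-centred points
classified by delivered dose (max dose inside the PTV; low dose 5-20 Gy;
no dose < 5 Gy) and by vascular topology ('Fed' when the vessel branches
downstream of the maximally irradiated vessel), at a mirrored contralateral
control, and at parenchymal points selected purely from ventilation maps
(consistently high HHV, consistently low LLV, and high-to-low HLV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np

from .core_io import (
    DoseGrid,
    EmptyROIError,
    ImageVolume,
    MetadataError,
    ROIMask,
    get_logger,
)
from .ventilation import VentilationClass, VentilationMap, ventilation_class_map

__all__ = [
    "LOW_DOSE_RANGE_GY",
    "NO_DOSE_MAX_GY",
    "VesselTree",
    "DoseLevel",
    "FedStatus",
    "ContourAssignment",
    "classify_dose_level",
    "fed_status",
    "mirror_contralateral",
    "select_ventilation_points",
    "sphere_mask",
]

log = get_logger("roi_dose")

NO_DOSE_MAX_GY = 5.0            # 'No Dose': receiving < 5 Gy (strict)
LOW_DOSE_RANGE_GY = (5.0, 20.0)  # 'Low Dose': receiving 5-20 Gy (inclusive)


class DoseLevel(Enum):
    NoDose = "NoDose"
    LowDose = "LowDose"
    MaxDose = "MaxDose"
    Unclassified = "Unclassified"  # > 20 Gy but outside the PTV; excluded


class FedStatus(Enum):
    Fed = "Fed"
    NotFed = "NotFed"


class VesselTree:
    """Rooted vascular tree: nodes with physical position, radius and dose.

    Connected, acyclic, single root (the main pulmonary inlet); child radii
    never exceed the parent radius.
    """

    def __init__(self, graph: nx.DiGraph, root: str):
        if root not in graph:
            raise KeyError(f"root {root!r} not in tree")
        if not nx.is_arborescence(graph):
            raise ValueError("vessel tree must be a connected, acyclic, single-root tree")
        for node, data in graph.nodes(data=True):
            if data.get("radius", 1.0) <= 0:
                raise ValueError(f"node {node!r} has non-positive radius")
        for parent, child in graph.edges:
            rp = graph.nodes[parent].get("radius")
            rc = graph.nodes[child].get("radius")
            if rp is not None and rc is not None and rc > rp + 1e-9:
                raise ValueError(f"child {child!r} radius exceeds parent {parent!r}")
        self.graph = graph
        self.root = root

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def position(self, node_id: str) -> np.ndarray:
        return np.asarray(self.graph.nodes[node_id]["position"], dtype=float)

    def radius(self, node_id: str) -> float:
        return float(self.graph.nodes[node_id]["radius"])

    def parent(self, node_id: str) -> str | None:
        preds = list(self.graph.predecessors(node_id))
        return preds[0] if preds else None

    def descendants(self, node_id: str) -> set[str]:
        return nx.descendants(self.graph, node_id)

    def mean_dose(self, node_id: str) -> float | None:
        return self.graph.nodes[node_id].get("mean_dose")

    def set_mean_dose(self, node_id: str, dose: float) -> None:
        self.graph.nodes[node_id]["mean_dose"] = float(dose)

    def max_dose_node(self) -> str:
        doses = {
            n: d for n, d in self.graph.nodes(data="mean_dose") if d is not None
        }
        if not doses:
            raise ValueError("no per-node doses annotated")
        return max(sorted(doses), key=lambda n: doses[n])

    # --- JSON serialization ----------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "root": self.root,
            "nodes": [
                {
                    "id": n,
                    "position": [float(v) for v in d["position"]],
                    "radius": float(d["radius"]),
                    **({"mean_dose": float(d["mean_dose"])} if "mean_dose" in d else {}),
                }
                for n, d in sorted(self.graph.nodes(data=True))
            ],
            "edges": sorted([list(e) for e in self.graph.edges]),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "VesselTree":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        g = nx.DiGraph()
        for node in payload["nodes"]:
            attrs = {"position": node["position"], "radius": node["radius"]}
            if "mean_dose" in node:
                attrs["mean_dose"] = node["mean_dose"]
            g.add_node(node["id"], **attrs)
        g.add_edges_from(payload["edges"])
        return cls(g, payload["root"])


@dataclass
class ContourAssignment:
    """A labelled analysis contour with its classification tuple."""

    label: str
    roi: ROIMask
    dose_level: DoseLevel | None = None
    fed: FedStatus | None = None
    vessel_node: str | None = None
    ventilation_pre: VentilationClass | None = None
    ventilation_post: VentilationClass | None = None
    centroid_mm: tuple[float, float, float] | None = None


# --------------------------------------------------------------------------
# Classification operations
# --------------------------------------------------------------------------

def classify_dose_level(roi: ROIMask, dose: DoseGrid, ptv: ROIMask) -> DoseLevel:
    """Dose level of an ROI: PTV membership first, then mean-dose rules.

    MaxDose if the ROI intersects the PTV; otherwise by mean ROI dose
    (< 5 Gy NoDose, 5-20 Gy inclusive LowDose).  An ROI above 20 Gy outside
    the PTV is flagged Unclassified and excluded (logged): the study design
    has no such category.
    """
    roi.check_congruent(dose.volume)
    ptv.check_congruent(dose.volume)
    if (roi.mask & ptv.mask).any():
        return DoseLevel.MaxDose
    mean_dose = float(dose.data[roi.mask].mean())
    if mean_dose < NO_DOSE_MAX_GY:
        return DoseLevel.NoDose
    if LOW_DOSE_RANGE_GY[0] <= mean_dose <= LOW_DOSE_RANGE_GY[1]:
        return DoseLevel.LowDose
    log.warning("ROI %s mean dose %.1f Gy outside PTV and above 20 Gy: Unclassified",
                roi.label, mean_dose)
    return DoseLevel.Unclassified


def fed_status(tree: VesselTree, vessel_id: str, max_dose_id: str) -> FedStatus:
    """Fed iff the vessel is a strict descendant of the max-dose vessel."""
    for node in (vessel_id, max_dose_id):
        if node not in tree.graph:
            raise KeyError(f"unknown vessel node {node!r}")
    return FedStatus.Fed if vessel_id in tree.descendants(max_dose_id) else FedStatus.NotFed


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def sphere_mask(reference: ImageVolume, centre_mm, radius_mm: float) -> np.ndarray:
    """Boolean ball of given physical radius around a physical centre."""
    ax = reference.physical_axes()
    dx = (ax[0] - centre_mm[0])[:, None, None]
    dy = (ax[1] - centre_mm[1])[None, :, None]
    dz = (ax[2] - centre_mm[2])[None, None, :]
    return dx * dx + dy * dy + dz * dz <= radius_mm * radius_mm


def _centroid_mm(mask: np.ndarray, reference: ImageVolume) -> np.ndarray:
    idx = np.argwhere(mask)
    centre_idx = idx.mean(axis=0)
    return np.asarray(reference.origin) + centre_idx * np.asarray(reference.spacing)


def mirror_contralateral(
    roi: ROIMask,
    ipsi_lung: ROIMask,
    contra_lung: ROIMask,
    reference: ImageVolume,
    max_snap_mm: float = 30.0,
) -> ROIMask:
    """Mirror an ipsilateral ROI across the mid-sagittal plane.

    The ROI centroid is reflected across the mid-sagittal (x) plane of the
    combined lung bounding box, snapped to the nearest contralateral lung
    voxel, and a same-volume spherical ROI is emitted, clipped to the
    contralateral lung.  A reflection landing more than ``max_snap_mm`` from
    the contralateral lung raises a placement warning in the log (with the
    distance) but still snaps.
    """
    if (ipsi_lung.mask & contra_lung.mask).any():
        raise ValueError("lungs must be disjoint")
    if not (roi.mask & ipsi_lung.mask).any():
        raise ValueError("ROI must lie in the ipsilateral lung")
    both = ipsi_lung.mask | contra_lung.mask
    xs = np.argwhere(both)[:, 0]
    ax = reference.physical_axes()
    mid_x = 0.5 * (ax[0][xs.min()] + ax[0][xs.max()])

    centre = _centroid_mm(roi.mask, reference)
    mirrored = centre.copy()
    mirrored[0] = 2.0 * mid_x - centre[0]

    contra_idx = np.argwhere(contra_lung.mask)
    contra_mm = np.asarray(reference.origin) + contra_idx * np.asarray(reference.spacing)
    d2 = np.sum((contra_mm - mirrored) ** 2, axis=1)
    nearest = int(np.argmin(d2))
    dist = float(np.sqrt(d2[nearest]))
    if dist > max_snap_mm:
        log.warning("mirrored centroid lands %.1f mm from the contralateral lung", dist)
    snapped = contra_mm[nearest]

    # Same-shape (equal-volume) sphere.
    voxel_vol = float(np.prod(reference.spacing))
    radius = (3.0 * roi.n_voxels * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    mask = sphere_mask(reference, snapped, radius) & contra_lung.mask
    if not mask.any():
        mask = np.zeros_like(contra_lung.mask)
        mask[tuple(contra_idx[nearest])] = True
    return ROIMask(mask=mask, label="CON", tissue=roi.tissue)


# --------------------------------------------------------------------------
# Ventilation-based point selection
# --------------------------------------------------------------------------

_CLASS_PAIRS = {
    "HHV": (VentilationClass.High, VentilationClass.High),
    "LLV": (VentilationClass.Low, VentilationClass.Low),
    "HLV": (VentilationClass.High, VentilationClass.Low),
}


def _sphere_kernel(spacing, radius_mm: float) -> np.ndarray:
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    return (grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= radius_mm ** 2


def select_ventilation_points(
    pre: VentilationMap,
    post: VentilationMap,
    ipsi_lung: ROIMask,
    radius_mm: float = 10.0,
    purity: float = 0.9,
) -> dict[str, ContourAssignment | None]:
    """Select the HHV / LLV / HLV parenchymal points from ventilation maps.

    For each class pair, candidate centres are lung voxels whose surrounding
    sphere (``radius_mm``, standing in for the study's ~1-inch histology
    sections) contains at least ``purity`` lung voxels of the required
    pre/post class pair - the 'region of similar ventilation values' rule.
    The centre maximising purity wins; ties break to the most-superior
    (highest z index), then most-anterior (lowest y), then most-right
    (lowest x) voxel, making the selection deterministic.  A class pair with
    no candidate is returned as None (its availability is subject-dependent),
    not an error.
    """
    if not pre.volume.congruent_with(post.volume):
        raise MetadataError("pre and post maps must be grid-congruent")
    ipsi_lung.check_congruent(pre.volume)
    if not ipsi_lung.mask.any():
        raise EmptyROIError("empty lung mask")

    from scipy.ndimage import convolve

    ref = pre.volume
    kernel = _sphere_kernel(ref.spacing, radius_mm).astype(float)
    cls_pre = ventilation_class_map(pre.data)
    cls_post = ventilation_class_map(post.data)
    lung = ipsi_lung.mask
    lung_count = convolve(lung.astype(float), kernel, mode="constant")

    out: dict[str, ContourAssignment | None] = {}
    for label, (want_pre, want_post) in _CLASS_PAIRS.items():
        ok = lung & (cls_pre == want_pre.value) & (cls_post == want_post.value)
        ok_count = convolve(ok.astype(float), kernel, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lung_count > 0, ok_count / lung_count, 0.0)
        candidates = ok & (frac >= purity)
        if not candidates.any():
            log.info("no %s candidate at purity %.2f; class unavailable", label, purity)
            out[label] = None
            continue
        idx = np.argwhere(candidates)
        scores = frac[candidates]
        best = scores.max()
        tied = idx[scores >= best - 1e-12]
        # most-superior (max z), then most-anterior (min y), then most-right (min x)
        order = np.lexsort((tied[:, 0], tied[:, 1], -tied[:, 2]))
        centre_idx = tied[order[0]]
        centre_mm = np.asarray(ref.origin) + centre_idx * np.asarray(ref.spacing)
        mask = sphere_mask(ref, centre_mm, radius_mm) & lung
        out[label] = ContourAssignment(
            label=label,
            roi=ROIMask(mask=mask, label=label, tissue="parenchyma"),
            ventilation_pre=want_pre,
            ventilation_post=want_post,
            centroid_mm=tuple(float(v) for v in centre_mm),
        )
    return out
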