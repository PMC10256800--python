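"""Contour classification: dose levels, fed topology, mirroring, point selection."""

import numpy as np
import networkx as nx
import pytest

from lungfx.core_io import DoseGrid, ImageVolume, ROIMask
from lungfx.roi_dose import (
    ContourAssignment,
    DoseLevel,
    FedStatus,
    VesselTree,
    classify_dose_level,
    fed_status,
    mirror_contralateral,
    select_ventilation_points,
    sphere_mask,
)
from lungfx.ventilation import VentilationMap


def _dose(shape=(8, 8, 8), value=0.0):
    return DoseGrid(volume=ImageVolume(data=np.full(shape, float(value)), spacing=(2, 2, 2)))


def _roi(shape=(8, 8, 8), label="MD", where=None):
    mask = np.zeros(shape, bool)
    if where is None:
        mask[2:4, 2:4, 2:4] = True
    else:
        mask[where] = True
    return ROIMask(mask=mask, label=label, tissue="vessel")


def _empty_ptv(shape=(8, 8, 8)):
    mask = np.zeros(shape, bool)
    mask[7, 7, 7] = True
    return ROIMask(mask=mask, label="vessel-bin", tissue="vessel")


@pytest.mark.parametrize(
    "mean_dose,expected",
    [
        (3.0, DoseLevel.NoDose),      # 'less than 5 Gy'
        (12.0, DoseLevel.LowDose),    # 'between 5 and 20 Gy'
        (5.0, DoseLevel.LowDose),     # inclusive lower bound
        (20.0, DoseLevel.LowDose),    # inclusive upper bound
        (4.999, DoseLevel.NoDose),
        (25.0, DoseLevel.Unclassified),
    ],
)
def test_classify_dose_level_mean_rules(mean_dose, expected):
    assert classify_dose_level(_roi(), _dose(value=mean_dose), _empty_ptv()) == expected


def test_ptv_membership_takes_precedence():
    roi = _roi()
    ptv = ROIMask(mask=roi.mask.copy(), label="vessel-bin", tissue="vessel")
    assert classify_dose_level(roi, _dose(value=1.0), ptv) == DoseLevel.MaxDose


# --------------------------------------------------------------------------
# fed status
# --------------------------------------------------------------------------

def _chain_tree():
    g = nx.DiGraph()
    for i, n in enumerate(["root", "a", "b", "c"]):
        g.add_node(n, position=(float(i), 0.0, 0.0), radius=4.0 - i * 0.5)
    g.add_edges_from([("root", "a"), ("a", "b"), ("b", "c")])
    g.add_node("s", position=(0.0, 1.0, 0.0), radius=3.0)
    g.add_edge("root", "s")
    return VesselTree(g, "root")


def test_fed_status_direct_descendant_and_sibling():
    tree = _chain_tree()
    assert fed_status(tree, "b", "a") == FedStatus.Fed
    assert fed_status(tree, "c", "a") == FedStatus.Fed     # deep grandchild
    assert fed_status(tree, "s", "a") == FedStatus.NotFed  # sibling branch
    assert fed_status(tree, "a", "a") == FedStatus.NotFed  # strict: not itself
    with pytest.raises(KeyError):
        fed_status(tree, "zz", "a")


def _walk_to_root_oracle(tree: VesselTree, node: str, ancestor: str) -> bool:
    """Exhaustive parent-walk: is `ancestor` on the strict root path of `node`?"""
    cur = tree.parent(node)
    while cur is not None:
        if cur == ancestor:
            return True
        cur = tree.parent(cur)
    return False


def test_fed_status_matches_ancestor_walk_oracle_on_random_trees(rng):
    for trial in range(10):
        n = int(rng.integers(10, 200))
        g = nx.DiGraph()
        g.add_node("n0", position=(0.0, 0.0, 0.0), radius=5.0)
        for i in range(1, n):
            parent = f"n{int(rng.integers(0, i))}"
            g.add_node(
                f"n{i}",
                position=tuple(rng.uniform(0, 100, 3)),
                radius=g.nodes[parent]["radius"] * 0.99,
            )
            g.add_edge(parent, f"n{i}")
        tree = VesselTree(g, "n0")
        for _ in range(20):
            a, b = (f"n{int(rng.integers(0, n))}" for _ in range(2))
            expected = FedStatus.Fed if _walk_to_root_oracle(tree, a, b) else FedStatus.NotFed
            assert fed_status(tree, a, b) == expected


def test_vessel_tree_invariants_and_json_round_trip(tmp_path):
    tree = _chain_tree()
    tree.set_mean_dose("a", 42.0)
    path = tmp_path / "tree.json"
    tree.to_json(path)
    back = VesselTree.from_json(path)
    assert set(back.node_ids) == set(tree.node_ids)
    assert back.mean_dose("a") == 42.0
    assert back.descendants("a") == tree.descendants("a")

    cyc = nx.DiGraph()
    cyc.add_node("a", position=(0, 0, 0), radius=1.0)
    cyc.add_node("b", position=(1, 0, 0), radius=1.0)
    cyc.add_edges_from([("a", "b"), ("b", "a")])
    with pytest.raises(ValueError):
        VesselTree(cyc, "a")

    bad = nx.DiGraph()
    bad.add_node("a", position=(0, 0, 0), radius=1.0)
    bad.add_node("b", position=(1, 0, 0), radius=2.0)  # child wider than parent
    bad.add_edge("a", "b")
    with pytest.raises(ValueError):
        VesselTree(bad, "a")


# --------------------------------------------------------------------------
# contralateral mirroring
# --------------------------------------------------------------------------

def test_mirror_contralateral_symmetric_phantom(small_phantom):
    ref = small_phantom.image
    ipsi = small_phantom.lung_mask("right")
    contra = small_phantom.lung_mask("left")
    centre = np.asarray(small_phantom.spec.lung_centres_mm[0]) + np.array([0, 5, 10])
    roi = ROIMask(mask=sphere_mask(ref, centre, 8.0) & ipsi.mask, label="MD", tissue="vessel")
    mirrored = mirror_contralateral(roi, ipsi, contra, ref)
    assert mirrored.label == "CON"
    assert mirrored.mask.any()
    assert not (mirrored.mask & ~contra.mask).any()
    # centroids equidistant from the mid-sagittal plane within one voxel
    ax = ref.physical_axes()[0]
    both = ipsi.mask | contra.mask
    xs = np.argwhere(both)[:, 0]
    mid_x = 0.5 * (ax[xs.min()] + ax[xs.max()])
    cx_roi = np.mean([ax[i] for i in np.argwhere(roi.mask)[:, 0]])
    cx_mir = np.mean([ax[i] for i in np.argwhere(mirrored.mask)[:, 0]])
    assert abs((mid_x - cx_roi) - (cx_mir - mid_x)) <= max(ref.spacing)


def test_mirror_requires_disjoint_lungs_and_membership(small_phantom):
    ref = small_phantom.image
    ipsi = small_phantom.lung_mask("right")
    with pytest.raises(ValueError):
        mirror_contralateral(
            ROIMask(mask=np.ones(ref.shape, bool), label="MD"), ipsi, ipsi, ref
        )


# --------------------------------------------------------------------------
# ventilation point selection
# --------------------------------------------------------------------------

def _maps_with_regions(phantom, specs):
    """Build pre/post LER maps with uniform background and value patches."""
    ref = phantom.image
    pre = np.full(ref.shape, 1.15)
    post = np.full(ref.shape, 1.15)
    for centre, v_pre, v_post in specs:
        patch = sphere_mask(ref, centre, 14.0)
        pre[patch] = v_pre
        post[patch] = v_post
    make = lambda d: VentilationMap(volume=ref.like(d))
    return make(pre), make(post)


def test_select_ventilation_points_finds_designed_regions(small_phantom):
    lc = np.asarray(small_phantom.spec.lung_centres_mm[0])
    specs = [
        (tuple(lc + [10, -18, 28]), 1.30, 1.30),   # HHV
        (tuple(lc + [-10, 18, 28]), 1.06, 1.06),   # LLV
        (tuple(lc + [0, 14, -30]), 1.24, 1.07),    # HLV
    ]
    pre, post = _maps_with_regions(small_phantom, specs)
    out = select_ventilation_points(pre, post, small_phantom.lung_mask("right"))
    for label, (centre, _, _) in zip(("HHV", "LLV", "HLV"), specs):
        assert out[label] is not None, label
        dist = np.linalg.norm(np.asarray(out[label].centroid_mm) - np.asarray(centre))
        assert dist <= 14.0, (label, dist)


def test_select_ventilation_points_single_class_lung(small_phantom):
    ref = small_phantom.image
    high = VentilationMap(volume=ref.like(np.full(ref.shape, 1.3)))
    out = select_ventilation_points(high, high, small_phantom.lung_mask("right"))
    assert out["HHV"] is not None
    assert out["LLV"] is None and out["HLV"] is None


def test_select_ventilation_points_noiseless_purity_and_determinism(small_phantom):
    lc = np.asarray(small_phantom.spec.lung_centres_mm[0])
    specs = [(tuple(lc + [0, 0, 25]), 1.30, 1.30)]
    pre, post = _maps_with_regions(small_phantom, specs)
    lung = small_phantom.lung_mask("right")
    at_09 = select_ventilation_points(pre, post, lung, purity=0.9)
    at_10 = select_ventilation_points(pre, post, lung, purity=1.0)
    again = select_ventilation_points(pre, post, lung, purity=0.9)
    assert at_09["HHV"].centroid_mm == at_10["HHV"].centroid_mm
    assert at_09["HHV"].centroid_mm == again["HHV"].centroid_mm
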