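import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from binderforge.backbone import build_chain_from_torsions
from binderforge.blueprint import TorsionTriple
from binderforge.errors import InvalidInputError
from binderforge.grafting import motif_to_model
from binderforge.scoring import (PseudoTarget, ScoreCard, contact_and_ddg_proxy,
                                 interface_buried_area, pair_weight, rank_designs,
                                 sasa, sphere_points)


def _target(atoms):
    return PseudoTarget(pd.DataFrame(atoms, columns=["x", "y", "z", "radius", "cls"]))


# ---------------------------------------------------------------------------
# SASA

def test_single_sphere_matches_analytic_area():
    area = sasa(np.zeros((1, 3)), np.array([1.7]), probe_radius=1.4,
                n_points=960).sum()
    assert area == pytest.approx(4 * math.pi * 3.1 ** 2, rel=0.01)


def test_distant_atoms_are_additive():
    coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    radii = np.array([1.7, 1.52])
    areas = sasa(coords, radii)
    isolated = [sasa(coords[i:i + 1], radii[i:i + 1]).sum() for i in range(2)]
    assert areas.sum() == pytest.approx(sum(isolated), rel=1e-9)


def test_two_overlapping_spheres_match_cap_formula():
    """Analytic two-sphere union: each sphere loses a spherical cap."""
    r1, r2, d, probe = 1.7, 1.52, 2.0, 1.4
    R1, R2 = r1 + probe, r2 + probe
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    got = sasa(coords, np.array([r1, r2]), probe, n_points=4000)
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    expected1 = 4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * h1
    expected2 = 4 * math.pi * R2 ** 2 - 2 * math.pi * R2 * h2
    assert got[0] == pytest.approx(expected1, rel=0.02)
    assert got[1] == pytest.approx(expected2, rel=0.02)


def test_sasa_converges_with_point_count(rng):
    coords = rng.normal(scale=3.0, size=(20, 3))
    radii = np.full(20, 1.7)
    coarse = sasa(coords, radii, n_points=960).sum()
    fine = sasa(coords, radii, n_points=4000).sum()
    assert abs(coarse - fine) / fine < 0.01


def test_sasa_handles_coincident_atoms():
    coords = np.zeros((2, 3))
    areas = sasa(coords, np.array([1.7, 1.7]))
    assert np.isfinite(areas).all()
    assert areas.sum() == 0.0  # each point lies inside the twin sphere


def test_sasa_input_validation():
    with pytest.raises(InvalidInputError):
        sasa(np.zeros((1, 3)), np.array([-1.0]))
    with pytest.raises(InvalidInputError):
        sasa(np.zeros((1, 3)), np.array([1.7]), n_points=50)


def test_sphere_points_quasi_uniform():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.abs(pts.mean(axis=0)).max() < 0.01


# ---------------------------------------------------------------------------
# buried area

def test_buried_area_zero_for_distant_parts():
    a = np.zeros((3, 3)) + [[0, 0, 0], [3, 0, 0], [6, 0, 0]]
    b = a + np.array([500.0, 0, 0])
    radii = np.full(3, 1.7)
    assert interface_buried_area(a, radii, b, radii) == pytest.approx(0.0, abs=1e-6)


def test_buried_area_positive_for_contacting_parts():
    a = np.array([[0.0, 0, 0]])
    b = np.array([[3.0, 0, 0]])
    r = np.array([1.7])
    assert interface_buried_area(a, r, b, r) > 10.0


def test_buried_area_invariant_under_joint_translation(rng):
    a = rng.normal(scale=2, size=(5, 3))
    b = a + np.array([4.0, 0, 0])
    r = np.full(5, 1.7)
    base = interface_buried_area(a, r, b, r)
    shift = np.array([17.0, -4.0, 2.0])
    moved = interface_buried_area(a + shift, r, b + shift, r)
    assert moved == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# contact pseudo-energy

def _single_residue_design(aa, xyz):
    model = build_chain_from_torsions([TorsionTriple(-60, -40, 180)] * 1,
                                      sequence=aa)
    # recenter the CA onto xyz
    shift = np.asarray(xyz, float) - model.residues[0].atom("CA")
    model.residues[0].coords = model.residues[0].coords + shift
    return model


def test_far_design_scores_zero():
    design = _single_residue_design("W", [100.0, 0, 0])
    target = _target([(0.0, 0, 0, 1.7, "hydrophobic")])
    card = contact_and_ddg_proxy(design, target)
    assert card.ddg_proxy == 0.0
    assert card.contact_surface == 0.0


def test_single_hydrophobic_pair_at_plateau():
    design = _single_residue_design("W", [3.0, 0, 0])
    target = _target([(0.0, 0, 0, 1.7, "hydrophobic")])
    card = contact_and_ddg_proxy(design, target)
    assert card.ddg_proxy == pytest.approx(-1.0, abs=1e-12)


def test_charge_complementarity_beats_swapped_charges(motif, pseudo_target):
    """RGD-like pose scores better (lower) than the same pose with the
    Arg/Asp classes swapped; verified against an exhaustive pairwise sum."""
    from binderforge.scoring import RESIDUE_CLASS, _distance_kernel
    model = motif_to_model(motif)
    card = contact_and_ddg_proxy(model, pseudo_target)

    swapped = motif_to_model(motif)
    seq = list(swapped.sequence)
    i_r, i_d = seq.index("R"), seq.index("D")
    seq[i_r], seq[i_d] = seq[i_d], seq[i_r]
    for r, aa in zip(swapped.residues, seq):
        r.aa = aa
    card_swapped = contact_and_ddg_proxy(swapped, pseudo_target)
    assert card.ddg_proxy < card_swapped.ddg_proxy

    # exhaustive oracle
    expected = 0.0
    for res in model.residues:
        for _, atom in pseudo_target.atoms.iterrows():
            d = np.linalg.norm(res.atom("CA") - atom[["x", "y", "z"]].to_numpy(float))
            expected += (pair_weight(RESIDUE_CLASS[res.aa], atom["cls"])
                         * float(_distance_kernel(np.array([d]))[0]))
    assert card.ddg_proxy == pytest.approx(expected, abs=1e-9)


def test_ddg_additive_over_disjoint_patches():
    design = _single_residue_design("W", [3.0, 0, 0])
    t_both = _target([(0.0, 0, 0, 1.7, "hydrophobic"),
                      (4.0, 3.0, 0, 1.52, "negative")])
    t_a = _target([(0.0, 0, 0, 1.7, "hydrophobic")])
    t_b = _target([(4.0, 3.0, 0, 1.52, "negative")])
    full = contact_and_ddg_proxy(design, t_both).ddg_proxy
    parts = (contact_and_ddg_proxy(design, t_a).ddg_proxy
             + contact_and_ddg_proxy(design, t_b).ddg_proxy)
    assert full == pytest.approx(parts, abs=1e-12)


def test_scores_invariant_under_joint_rigid_motion(motif, pseudo_target):
    model = motif_to_model(motif)
    base = contact_and_ddg_proxy(model, pseudo_target)
    rot = Rotation.random(random_state=4).as_matrix()
    trans = np.array([8.0, 1.0, -5.0])
    moved_model = model.transformed(rot, trans)
    atoms = pseudo_target.atoms.copy()
    xyz = atoms[["x", "y", "z"]].to_numpy() @ rot.T + trans
    atoms[["x", "y", "z"]] = xyz
    moved = contact_and_ddg_proxy(moved_model, PseudoTarget(atoms))
    # distance-based quantities are exactly invariant
    assert moved.ddg_proxy == pytest.approx(base.ddg_proxy, abs=1e-9)
    assert moved.clash_count == base.clash_count
    # finite sphere sampling makes areas approximately rotation-invariant
    assert moved.sasa_total == pytest.approx(base.sasa_total, rel=0.02)
    assert moved.interface_buried_area == pytest.approx(
        base.interface_buried_area, rel=0.05, abs=2.0)


def test_scorecard_invariant_contact_below_buried(motif, pseudo_target):
    card = contact_and_ddg_proxy(motif_to_model(motif), pseudo_target)
    assert 0.0 <= card.contact_surface <= card.interface_buried_area


def test_clashing_pose_flagged_but_scored():
    design = _single_residue_design("W", [1.0, 0, 0])
    target = _target([(0.0, 0, 0, 1.7, "hydrophobic")])
    card = contact_and_ddg_proxy(design, target)
    assert not card.passes
    assert card.clash_count > 0
    assert card.ddg_proxy < 0  # energy still reported


# ---------------------------------------------------------------------------
# ranking

def _card(i, ddg, contact=0.0, passes=True):
    return ScoreCard(f"d{i}", ddg, 1000.0, max(contact, 0.0), contact, 0, passes)


def test_rank_orders_by_energy_then_contact():
    cards = [_card(0, -1.0, 10), _card(1, -3.0, 5), _card(2, -1.0, 20)]
    ranked = rank_designs(cards)
    assert [c.design_id for c in ranked] == ["d1", "d2", "d0"]


def test_rank_deterministic_under_permutation():
    cards = [_card(i, ddg) for i, ddg in enumerate([-2.0, -5.0, -1.0, -5.0])]
    ranked = rank_designs(cards)
    ranked_perm = rank_designs(list(reversed(cards)))
    assert [c.design_id for c in ranked] == [c.design_id for c in ranked_perm]


def test_rank_thresholds_can_reject_everything():
    cards = [_card(0, 5.0), _card(1, 2.0)]
    assert rank_designs(cards, {"ddg_max": -1.0}) == []


def test_dominated_card_never_outranks_dominator():
    dominator = _card(0, -5.0, 30)
    dominated = _card(1, -2.0, 10)
    ranked = rank_designs([dominated, dominator])
    assert ranked.index(dominator) < ranked.index(dominated)


def test_pseudo_target_validation():
    with pytest.raises(InvalidInputError):
        _target([(0.0, 0, 0, 0.5, "hydrophobic")])  # radius too small
    with pytest.raises(InvalidInputError):
        _target([(0.0, 0, 0, 1.7, "greasy")])  # unknown class
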