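import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from binderforge.backbone import (
    AssemblyConfig, GeometryParams, assemble_stagewise, build_chain_from_torsions,
    cavity_volume, check_clashes, compactness_and_cavity_filter, default_rg_max,
    dihedral, measure_torsions, radius_of_gyration, sample_torsions_for_segment)
from binderforge.blueprint import SegmentSpec, TorsionTriple, classify_abego
from binderforge.errors import ConfigurationError, DegenerateGeometryError, InvalidInputError
from binderforge.fixtures import make_topology_stats
from binderforge.blueprint import enumerate_blueprints


def random_torsions(rng, n):
    return [TorsionTriple(rng.uniform(-180, 180), rng.uniform(-180, 180),
                          rng.uniform(120, 180) * rng.choice([-1, 1]))
            for _ in range(n)]


# ---------------------------------------------------------------------------
# chain construction

def test_helix_geometry(helix8):
    ca = helix8.ca_coords
    steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.allclose(steps, 3.80, atol=0.02)
    # helical rise per residue along the principal axis
    centered = ca - ca.mean(axis=0)
    axis = np.linalg.svd(centered)[2][0]
    rise = np.abs(np.diff(centered @ axis)).mean()
    assert 1.4 < rise < 1.6


def test_peptide_bond_length_exact():
    m = build_chain_from_torsions([TorsionTriple(-80, 100, 180)] * 2)
    d = np.linalg.norm(m.residues[0].atom("C") - m.residues[1].atom("N"))
    assert abs(d - 1.329) < 1e-12


def test_empty_chain_rejected():
    with pytest.raises(InvalidInputError):
        build_chain_from_torsions([])


@pytest.mark.parametrize("seed", range(8))
def test_build_measure_round_trip(seed):
    """Interior torsions reconstruct to well below a micro-degree."""
    rng = np.random.default_rng(seed)
    torsions = random_torsions(rng, 15)
    model = build_chain_from_torsions(torsions)
    measured = measure_torsions(model)
    for orig, got in list(zip(torsions, measured))[1:-1]:
        assert abs(orig.phi - got.phi) < 1e-6
        assert abs(orig.psi - got.psi) < 1e-6
        assert abs(orig.omega - got.omega) < 1e-6
    # terminals: ψ/ω of the last and φ of the first are junction angles
    assert abs(measured[0].psi - torsions[0].psi) < 1e-6
    assert abs(measured[-1].phi - torsions[-1].phi) < 1e-6


def test_measure_needs_two_residues():
    m = build_chain_from_torsions([TorsionTriple(-60, -40, 180)])
    with pytest.raises(InvalidInputError):
        measure_torsions(m)


def test_dihedral_conventions():
    # cis arrangement of four coplanar points -> 0 degrees
    p = [np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]),
         np.array([2.0, 0.0, 0.0]), np.array([2.0, 1.0, 0.0])]
    assert abs(dihedral(*p)) < 1e-12
    with pytest.raises(DegenerateGeometryError):
        dihedral(np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]),
                 np.array([3.0, 0, 0]))


def test_ideal_strand_classifies_as_B():
    m = build_chain_from_torsions([TorsionTriple(-120, 130, 180)] * 6)
    letters = [classify_abego(t) for t in measure_torsions(m)[1:-1]]
    assert letters == ["B"] * 4


def test_geometry_params_validated():
    with pytest.raises(InvalidInputError):
        GeometryParams(bond_n_ca=-1.0)
    with pytest.raises(InvalidInputError):
        GeometryParams(angle_n_ca_c=190.0)


# ---------------------------------------------------------------------------
# torsion sampling

def test_sampled_torsions_classify_to_requested_letters(rng):
    seg = SegmentSpec("L2", "L", 2, "GB")
    tors = sample_torsions_for_segment(seg, 1)
    assert [classify_abego(t) for t in tors] == ["G", "B"]
    helix = sample_torsions_for_segment(SegmentSpec("H1", "H", 10), 7)
    assert len(helix) == 10
    assert all(classify_abego(t) == "A" for t in helix)


def test_sampling_deterministic_per_seed():
    seg = SegmentSpec("L1", "L", 6, "GGBAEE")
    a = sample_torsions_for_segment(seg, 42)
    b = sample_torsions_for_segment(seg, 42)
    assert a == b
    assert a != sample_torsions_for_segment(seg, 43)


def test_cis_sampling_requires_opt_in():
    seg = SegmentSpec("L2", "L", 2, "GO")
    with pytest.raises(ConfigurationError):
        sample_torsions_for_segment(seg, 0)
    tors = sample_torsions_for_segment(seg, 0, allow_cis=True)
    assert classify_abego(tors[1]) == "O"


# ---------------------------------------------------------------------------
# filters

def test_clash_count_trivials(helix8):
    single = build_chain_from_torsions([TorsionTriple(-60, -40, 180)])
    assert check_clashes(single) == 0
    assert check_clashes(helix8, 2.8) == 0
    # two superposed copies of a residue, two residues apart in sequence
    m = build_chain_from_torsions([TorsionTriple(-57, -47, 180)] * 3)
    m.residues[2].coords = m.residues[0].coords.copy()
    assert check_clashes(m) > 0


def test_clash_count_matches_bruteforce(rng):
    model = build_chain_from_torsions(random_torsions(rng, 10))
    threshold = 3.0
    brute = 0
    for i, ri in enumerate(model.residues):
        for j, rj in enumerate(model.residues):
            if j - i < 2:
                continue
            brute += int((cdist(ri.coords, rj.coords) < threshold).sum())
    assert check_clashes(model, threshold) == brute


def test_radius_of_gyration_matches_direct_formula(rng):
    model = build_chain_from_torsions(random_torsions(rng, 20))
    ca = model.ca_coords
    expected = math.sqrt(((ca - ca.mean(0)) ** 2).sum(1).mean())
    assert abs(radius_of_gyration(model) - expected) < 1e-12


def test_extended_chain_fails_compactness():
    extended = build_chain_from_torsions([TorsionTriple(-120, 130, 180)] * 30)
    ok, metrics = compactness_and_cavity_filter(extended, rg_max=12.0)
    assert not ok
    assert metrics["radius_of_gyration"] > 12.0


def test_single_residue_passes_filter():
    m = build_chain_from_torsions([TorsionTriple(-60, -40, 180)])
    ok, metrics = compactness_and_cavity_filter(m)
    assert ok
    assert metrics["cavity_volume"] == 0.0
    assert metrics["radius_of_gyration"] < 1.5


def _shell_model():
    """A hollow cube of pseudo-residues enclosing an empty interior."""
    from binderforge.backbone import BackboneModel, Residue
    pts = []
    grid = np.arange(-6.0, 6.1, 2.0)
    for x in grid:
        for y in grid:
            for z in grid:
                if max(abs(x), abs(y), abs(z)) >= 6.0:  # surface only
                    pts.append((x, y, z))
    residues = [Residue(i + 1, "G", np.tile(np.array(p), (4, 1)))
                for i, p in enumerate(pts)]
    return BackboneModel(residues)


def test_hollow_shell_has_cavity_matching_voxel_oracle():
    model = _shell_model()
    vol = cavity_volume(model, grid_spacing=1.0, probe_radius=1.4,
                        atom_radius=1.7)
    assert vol > 0
    # independent brute-force voxel scan with the same 5-of-6 enclosure rule
    xyz = model.coords
    lo = xyz.min(0) - 2.0
    hi = xyz.max(0) + 2.0
    shape = np.maximum(np.ceil((hi - lo) / 1.0).astype(int), 1)
    occupied = np.zeros(tuple(shape), bool)
    centers = {}
    for ix in range(shape[0]):
        for iy in range(shape[1]):
            for iz in range(shape[2]):
                c = lo + 1.0 * (np.array([ix, iy, iz]) + 0.5)
                centers[ix, iy, iz] = c
                occupied[ix, iy, iz] = np.linalg.norm(xyz - c, axis=1).min() <= 3.1
    brute = 0
    for (ix, iy, iz), c in centers.items():
        if occupied[ix, iy, iz]:
            continue
        enclosed = sum([
            occupied[:ix, iy, iz].any(), occupied[ix + 1:, iy, iz].any(),
            occupied[ix, :iy, iz].any(), occupied[ix, iy + 1:, iz].any(),
            occupied[ix, iy, :iz].any(), occupied[ix, iy, iz + 1:].any()])
        brute += enclosed >= 5
    assert vol == pytest.approx(float(brute), abs=1e-9)


def test_filters_invariant_under_rigid_motion(rng):
    model = build_chain_from_torsions(random_torsions(rng, 15))
    rot = Rotation.random(random_state=3).as_matrix()
    trans = np.array([11.0, -7.0, 3.0])
    moved = model.transformed(rot, trans)
    assert check_clashes(moved) == check_clashes(model)
    assert radius_of_gyration(moved) == pytest.approx(
        radius_of_gyration(model), abs=1e-9)
    # the cavity grid is anchored to the model's bounding box, so pure
    # translations leave the voxelization (and the volume) unchanged
    shifted = model.transformed(np.eye(3), trans)
    assert cavity_volume(shifted) == pytest.approx(cavity_volume(model), abs=1e-9)


# ---------------------------------------------------------------------------
# stagewise assembly

@pytest.fixture(scope="module")
def top_blueprint():
    stats = make_topology_stats(0)
    return enumerate_blueprints(stats, 1, 1, 1)[0]


def test_assembly_returns_three_reports_in_order(top_blueprint):
    _, reports = assemble_stagewise(top_blueprint, n_tries_per_stage=5, rng_seed=0)
    assert [r.stage for r in reports] == [1, 2, 3]
    assert reports[0].elements == ("E1", "L1", "H1")
    assert reports[1].elements == ("L2", "E2", "L3", "E3")
    assert reports[2].elements == ("L4", "H2", "L5", "E4")


def test_assembly_zero_tries_yields_empty(top_blueprint):
    survivors, reports = assemble_stagewise(top_blueprint, n_tries_per_stage=0,
                                            rng_seed=0)
    assert survivors == []
    assert all(r.generated == 0 for r in reports)


def test_assembly_conserves_length_and_counts(top_blueprint):
    survivors, reports = assemble_stagewise(top_blueprint,
                                            n_tries_per_stage=2500, rng_seed=0)
    assert survivors, "expected at least one survivor at this sampling depth"
    for model in survivors:
        assert len(model) == top_blueprint.total_length
        assert check_clashes(model) == 0
    for r in reports:
        assert r.passed <= r.generated
        assert (r.failed_clash + r.failed_pairing + r.failed_compactness
                + r.failed_cavity + r.passed) == r.generated


def test_assembly_deterministic_per_seed(top_blueprint):
    s1, r1 = assemble_stagewise(top_blueprint, n_tries_per_stage=1200, rng_seed=7)
    s2, r2 = assemble_stagewise(top_blueprint, n_tries_per_stage=1200, rng_seed=7)
    assert [r.passed for r in r1] == [r.passed for r in r2]
    assert len(s1) == len(s2)
    for a, b in zip(s1, s2):
        assert np.array_equal(a.coords, b.coords)


def test_assembly_motif_length_must_fit(top_blueprint, motif):
    bad = motif.transformed(np.eye(3), np.zeros(3))
    bad.residues = bad.residues[:3]  # now far from the L1 slot length
    with pytest.raises(InvalidInputError):
        assemble_stagewise(top_blueprint, motif=bad, n_tries_per_stage=1)


def test_assembly_around_motif_pins_its_coordinates(top_blueprint, motif):
    survivors, _ = assemble_stagewise(
        top_blueprint, motif=motif, n_tries_per_stage=2500, rng_seed=1)
    assert survivors
    fixed = np.concatenate([r.coords[:3] for r in motif.residues])
    for model in survivors:
        got = np.concatenate([model.residues[i].coords[:3] for i in range(5, 11)])
        assert np.abs(got - fixed).max() < 1e-6


def test_default_rg_max_scales_with_length():
    assert default_rg_max(54) == pytest.approx(1.3 * (0.395 * 54 ** 0.6 + 7.257))
    assert default_rg_max(100) > default_rg_max(50)
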