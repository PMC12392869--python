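"""All-backbone model construction from torsions (NeRF chain growth).

Backbone models carry N, CA, C, O coordinates per residue.  Chains are
grown residue by residue in internal coordinates with ideal covalent
geometry; φ/ψ/ω torsions are the only degrees of freedom.  The module
also provides the geometric filters used during stagewise assembly:
steric clash counting, β-strand pairing, radius of gyration and a
voxel-grid cavity detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .blueprint import (Blueprint, SegmentSpec, TorsionTriple, classify_abego,
                        normalize_angle)
from .errors import (ConfigurationError, DegenerateGeometryError,
                     InvalidInputError)

__all__ = [
    "GeometryParams",
    "Residue",
    "BackboneModel",
    "StageReport",
    "build_chain_from_torsions",
    "measure_torsions",
    "dihedral",
    "place_atom",
    "sample_torsions_for_segment",
    "assemble_stagewise",
    "check_clashes",
    "strand_pairing_contacts",
    "radius_of_gyration",
    "cavity_volume",
    "compactness_and_cavity_filter",
    "default_rg_max",
    "CLASS_TORSION_MEANS",
    "CLASS_TORSION_SIGMAS",
]


@dataclass(frozen=True)
class GeometryParams:
    """Ideal backbone covalent geometry (lengths in Å, angles in degrees)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca"):
            if not 0 < getattr(self, name) < 180:
                raise InvalidInputError(f"{name} must lie in (0, 180)")


IDEAL_GEOMETRY = GeometryParams()

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """One residue: 1-based index, one-letter code, 4x3 backbone coords."""

    index: int
    aa: str
    coords: np.ndarray  # rows N, CA, C, O

    def atom(self, name: str) -> np.ndarray:
        return self.coords[BACKBONE_ATOMS.index(name)]


@dataclass
class BackboneModel:
    """An ordered backbone chain with provenance of how it was built."""

    residues: list[Residue]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """All backbone atom coordinates, shape (4*n_residues, 3)."""
        return np.concatenate([r.coords for r in self.residues], axis=0)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.stack([r.atom("CA") for r in self.residues], axis=0)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneModel":
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        residues = [Residue(r.index, r.aa, r.coords @ rot.T + t) for r in self.residues]
        return BackboneModel(residues, dict(self.provenance))

    def slice(self, start: int, stop: int) -> "BackboneModel":
        """Residues [start, stop) by 0-based position, reindexed from 1."""
        residues = [Residue(i + 1, r.aa, r.coords.copy())
                    for i, r in enumerate(self.residues[start:stop])]
        return BackboneModel(residues, dict(self.provenance))


@dataclass
class StageReport:
    """Bookkeeping of one assembly stage: what was built and filtered."""

    stage: int
    elements: tuple[str, ...]
    generated: int = 0
    passed: int = 0
    failed_clash: int = 0
    failed_pairing: int = 0
    failed_compactness: int = 0
    failed_cavity: int = 0

    def __post_init__(self):
        if self.stage not in (1, 2, 3):
            raise InvalidInputError("stage index must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# internal-coordinate construction

def _place_atom_scalar(ax, ay, az, bx, by, bz, cx, cy, cz,
                       bond, angle_deg, torsion_deg):
    """Scalar NeRF placement (hot path of chain growth)."""
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    if norm < 1e-12:
        raise DegenerateGeometryError("colinear reference atoms for placement")
    nx, ny, nz = nx / norm, ny / norm, nz / norm
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d0 = -bond * math.cos(ang)
    d1 = bond * math.sin(ang) * math.cos(tor)
    d2 = bond * math.sin(ang) * math.sin(tor)
    return (cx + d0 * bcx + d1 * mx + d2 * nx,
            cy + d0 * bcy + d1 * my + d2 * ny,
            cz + d0 * bcz + d1 * mz + d2 * nz)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C, the C-D bond length, B-C-D angle and
    A-B-C-D torsion (natural extension reference frame)."""
    return np.array(_place_atom_scalar(*a, *b, *c, bond, angle_deg, torsion_deg))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("colinear atom quadruple has no dihedral")
    b1n = b1 / np.linalg.norm(b1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1n))
    return normalize_angle(math.degrees(math.atan2(y, x)))


def _place_carbonyl_oxygens(n_xyz, ca_xyz, c_xyz, geometry: GeometryParams) -> np.ndarray:
    """O(i) sits in the CA(i)-C(i)-N(i+1) plane opposite N(i+1); the
    terminal O continues the CA->C direction bisector against N."""
    n_res = len(ca_xyz)
    n_ref = np.concatenate([n_xyz[1:], n_xyz[-1:]])  # terminal: own N
    u_ca = ca_xyz - c_xyz
    u_ca /= np.linalg.norm(u_ca, axis=1, keepdims=True)
    u_next = n_ref - c_xyz
    u_next /= np.linalg.norm(u_next, axis=1, keepdims=True)
    bisector = u_ca + u_next
    norm = np.linalg.norm(bisector, axis=1, keepdims=True)
    norm[norm < 1e-9] = 1.0
    return c_xyz - geometry.bond_c_o * bisector / norm


def build_chain_from_torsions(
    torsions: list[TorsionTriple],
    geometry: GeometryParams = IDEAL_GEOMETRY,
    sequence: str | None = None,
) -> BackboneModel:
    """Grow an N/CA/C/O backbone from per-residue (φ, ψ, ω) torsions.

    Residue i's φ spans C(i-1)-N(i)-CA(i)-C(i), ψ spans N(i)-CA(i)-C(i)-N(i+1)
    and ω spans CA(i)-C(i)-N(i+1)-CA(i+1); φ of the first residue and ψ/ω of
    the last are therefore not consumed.  ``measure_torsions`` on the result
    reproduces the inputs for all defined angles.
    """
    n_res = len(torsions)
    if n_res < 1:
        raise InvalidInputError("need at least one residue")
    if sequence is None:
        sequence = "G" * n_res
    if len(sequence) != n_res:
        raise InvalidInputError("sequence length does not match torsion count")

    n_xyz = np.empty((n_res, 3))
    ca_xyz = np.empty((n_res, 3))
    c_xyz = np.empty((n_res, 3))

    # first residue in a canonical frame
    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (geometry.bond_n_ca, 0.0, 0.0)
    ang = math.radians(geometry.angle_n_ca_c)
    c_xyz[0] = ca_xyz[0] + geometry.bond_ca_c * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])

    g = geometry
    n_i = tuple(n_xyz[0])
    ca_i = tuple(ca_xyz[0])
    c_i = tuple(c_xyz[0])
    for i in range(n_res - 1):
        n_next = _place_atom_scalar(*n_i, *ca_i, *c_i,
                                    g.bond_c_n, g.angle_ca_c_n, torsions[i].psi)
        ca_next = _place_atom_scalar(*ca_i, *c_i, *n_next,
                                     g.bond_n_ca, g.angle_c_n_ca, torsions[i].omega)
        c_next = _place_atom_scalar(*c_i, *n_next, *ca_next,
                                    g.bond_ca_c, g.angle_n_ca_c, torsions[i + 1].phi)
        n_xyz[i + 1], ca_xyz[i + 1], c_xyz[i + 1] = n_next, ca_next, c_next
        n_i, ca_i, c_i = n_next, ca_next, c_next

    o_xyz = _place_carbonyl_oxygens(n_xyz, ca_xyz, c_xyz, geometry)
    residues = [
        Residue(i + 1, sequence[i],
                np.stack([n_xyz[i], ca_xyz[i], c_xyz[i], o_xyz[i]]))
        for i in range(n_res)
    ]
    return BackboneModel(residues)


def measure_torsions(model: BackboneModel) -> list[TorsionTriple]:
    """Measure per-residue (φ, ψ, ω) with standard dihedral definitions.

    φ of the first residue and ψ/ω of the last residue are undefined for
    an isolated chain; they are reported as placeholder values (0° and
    trans respectively) that consumers must not interpret as geometry.
    """
    n_res = len(model)
    if n_res < 2:
        raise InvalidInputError("need at least two residues to measure torsions")
    out = []
    res = model.residues
    for i in range(n_res):
        phi = dihedral(res[i - 1].atom("C"), res[i].atom("N"),
                       res[i].atom("CA"), res[i].atom("C")) if i > 0 else 0.0
        if i + 1 < n_res:
            psi = dihedral(res[i].atom("N"), res[i].atom("CA"),
                           res[i].atom("C"), res[i + 1].atom("N"))
            omega = dihedral(res[i].atom("CA"), res[i].atom("C"),
                             res[i + 1].atom("N"), res[i + 1].atom("CA"))
        else:
            psi, omega = 0.0, 180.0 - 1e-9
        out.append(TorsionTriple(phi, psi, omega))
    return out


# ---------------------------------------------------------------------------
# torsion sampling

#: Per-ABEGO-class (φ, ψ) means in degrees for torsion sampling.
CLASS_TORSION_MEANS = {
    "A": (-63.0, -42.0),
    "B": (-120.0, 130.0),
    "G": (60.0, 35.0),
    "E": (120.0, -130.0),
}
#: Per-class Gaussian widths (degrees).
CLASS_TORSION_SIGMAS = {"A": 8.0, "B": 15.0, "G": 10.0, "E": 15.0}

_SS_CLASS = {"H": "A", "E": "B"}


def _draw_class_torsion(letter: str, rng: np.random.Generator,
                        sigma_scale: float = 1.0) -> TorsionTriple:
    mu_phi, mu_psi = CLASS_TORSION_MEANS[letter]
    sigma = CLASS_TORSION_SIGMAS[letter] * sigma_scale
    for _ in range(1000):  # rejection to the class bin
        t = TorsionTriple(rng.normal(mu_phi, sigma), rng.normal(mu_psi, sigma))
        if classify_abego(t) == letter:
            return t
    raise ConfigurationError(f"rejection sampling for class {letter} did not converge")


def sample_torsions_for_segment(
    seg: SegmentSpec,
    rng_seed: int | np.random.Generator,
    sigma_scale: float = 1.0,
    allow_cis: bool = False,
) -> list[TorsionTriple]:
    """Draw per-residue torsions consistent with a segment's constraints.

    Helices draw near (−57, −47), strands near (−120, 130); loop residues
    draw from the per-class Gaussian of their ABEGO letter, rejected until
    ``classify_abego`` reproduces the requested letter.  Deterministic for
    a given seed.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    letters = seg.abego if seg.ss_type == "L" else _SS_CLASS[seg.ss_type] * seg.length
    out = []
    for letter in letters:
        if letter == "O":
            if not allow_cis:
                raise ConfigurationError(
                    "cis-ω (ABEGO 'O') requested without cis support enabled")
            out.append(TorsionTriple(-75.0, 160.0, 0.0))
            continue
        out.append(_draw_class_torsion(letter, rng, sigma_scale))
    return out


# ---------------------------------------------------------------------------
# geometric filters

def check_clashes(model: BackboneModel, min_distance: float = 2.8) -> int:
    """Count non-bonded backbone atom pairs closer than ``min_distance``.

    Pairs within the same residue or adjacent residues are excluded
    (sequence separation of at least 2 residues is required).
    """
    if len(model) == 0:
        raise InvalidInputError("empty model")
    xyz = model.coords
    res_idx = np.repeat(np.arange(len(model)), 4)
    d = cdist(xyz, xyz)
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    mask = (sep >= 2) & (d < min_distance)
    return int(np.triu(mask, k=1).sum())


def strand_pairing_contacts(
    model: BackboneModel,
    strand_a: tuple[int, int],
    strand_b: tuple[int, int],
    max_no_distance: float = 3.5,
) -> int:
    """Count inter-strand backbone N(i)···O(j) hydrogen-bond-like contacts.

    ``strand_a``/``strand_b`` are half-open 0-based residue ranges.  Both
    N(a)···O(b) and N(b)···O(a) directions are counted; a pairing check
    passes when at least two such contacts exist (caller's criterion).
    """
    res = model.residues
    n_a = np.stack([res[i].atom("N") for i in range(*strand_a)])
    o_a = np.stack([res[i].atom("O") for i in range(*strand_a)])
    n_b = np.stack([res[i].atom("N") for i in range(*strand_b)])
    o_b = np.stack([res[i].atom("O") for i in range(*strand_b)])
    contacts = int((cdist(n_a, o_b) < max_no_distance).sum())
    contacts += int((cdist(n_b, o_a) < max_no_distance).sum())
    return contacts


def radius_of_gyration(model: BackboneModel) -> float:
    """Radius of gyration over CA atoms (Å)."""
    ca = model.ca_coords
    center = ca.mean(axis=0)
    return float(np.sqrt(((ca - center) ** 2).sum(axis=1).mean()))


def default_rg_max(n_residues: int, slack: float = 1.3) -> float:
    """Compactness threshold: empirical folded-protein Rg scaling
    (0.395·N^(3/5) + 7.257 Å) with a multiplicative slack for
    backbone-only models."""
    return slack * (0.395 * n_residues ** 0.6 + 7.257)


def cavity_volume(
    model: BackboneModel,
    grid_spacing: float = 1.0,
    probe_radius: float = 1.4,
    atom_radius: float = 1.7,
) -> float:
    """Interior void volume (Å^3) by voxel scan.

    A voxel is empty when its center is farther than atom_radius + probe
    from every backbone atom; an empty voxel counts as cavity when
    occupied voxels enclose it along at least 5 of the 6 axis directions.
    """
    xyz = model.coords
    lo = xyz.min(axis=0) - 2.0
    hi = xyz.max(axis=0) + 2.0
    shape = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int), 1)
    axes = [lo[k] + grid_spacing * (np.arange(shape[k]) + 0.5) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    dmin = cdist(centers, xyz).min(axis=1).reshape(tuple(shape))
    occupied = dmin <= (atom_radius + probe_radius)

    # prefix scans: does an occupied voxel exist somewhere along each ray?
    enclosed = np.zeros(tuple(shape), dtype=np.int8)
    for axis in range(3):
        fwd = np.flip(np.maximum.accumulate(np.flip(occupied, axis), axis), axis)
        bwd = np.maximum.accumulate(occupied, axis)
        enclosed += fwd.astype(np.int8) + bwd.astype(np.int8)
    cavity = (~occupied) & (enclosed >= 5)
    return float(cavity.sum()) * grid_spacing ** 3


def default_cavity_max(n_residues: int, per_residue: float = 8.0) -> float:
    """Cavity-volume threshold sized for backbone-only models.

    Without side chains the space they would fill registers as interior
    void (about 6–7 Å^3 per residue in compact all-backbone folds), so
    the budget scales with chain length rather than being an absolute
    few-voxel allowance.
    """
    return per_residue * n_residues


def compactness_and_cavity_filter(
    model: BackboneModel,
    rg_max: float | None = None,
    cavity_volume_max: float | None = None,
) -> tuple[bool, dict]:
    """Pass/fail on compactness (CA radius of gyration) and interior voids."""
    if rg_max is None:
        rg_max = default_rg_max(len(model))
    if cavity_volume_max is None:
        cavity_volume_max = default_cavity_max(len(model))
    rg = radius_of_gyration(model)
    cav = cavity_volume(model)
    metrics = {"radius_of_gyration": rg, "cavity_volume": cav,
               "rg_max": rg_max, "cavity_volume_max": cavity_volume_max}
    return (rg <= rg_max) and (cav <= cavity_volume_max), metrics


# ---------------------------------------------------------------------------
# stagewise assembly

_STAGE_ELEMENTS = (
    ("E1", "L1", "H1"),
    ("L2", "E2", "L3", "E3"),
    ("L4", "H2", "L5", "E4"),
)


@dataclass
class AssemblyConfig:
    """Tunable thresholds of the stagewise builder.

    The E2/E3 hairpin must form backbone N···O contacts; the long-range
    E1/E2 sheet closure is checked as CA proximity plus parallel strand
    orientation, since torsion sampling without minimization cannot
    realize hydrogen-bond registry across the helix.
    """

    clash_min_distance: float = 2.8
    pairing_max_no_distance: float = 3.5   # hairpin N···O contact distance
    pairing_min_contacts: int = 2          # hairpin contacts required
    sheet_max_ca_distance: float = 6.5     # E1/E2 closure: min CA-CA
    sheet_min_dot: float = 0.0             # E1/E2 strand direction dot > this
    rg_max: float | None = None            # None -> default_rg_max(n)
    cavity_volume_max: float | None = None  # None -> default_cavity_max(n)
    sigma_scale: float = 1.0
    max_carryover: int = 16                # survivors carried into the next stage


def _segment_ranges(bp: Blueprint) -> dict[str, tuple[int, int]]:
    ranges = {}
    pos = 0
    for seg in bp.segments:
        ranges[seg.element_id] = (pos, pos + seg.length)
        pos += seg.length
    return ranges


def _motif_torsions(motif) -> list[TorsionTriple]:
    if getattr(motif, "torsions", None):
        return list(motif.torsions)
    from .grafting import motif_to_model  # local import avoids a cycle
    return measure_torsions(motif_to_model(motif))


def _sheet_closure_ok(model: BackboneModel, range_a, range_b,
                      cfg: "AssemblyConfig") -> bool:
    """E1/E2 closure: strands near each other and running parallel."""
    ca = model.ca_coords
    ca_a, ca_b = ca[range_a[0]:range_a[1]], ca[range_b[0]:range_b[1]]
    if cdist(ca_a, ca_b).min() > cfg.sheet_max_ca_distance:
        return False
    va = ca_a[-1] - ca_a[0]
    vb = ca_b[-1] - ca_b[0]
    dot = float(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return dot > cfg.sheet_min_dot


def assemble_stagewise(
    bp: Blueprint,
    motif=None,
    n_tries_per_stage: int = 50,
    rng_seed: int = 0,
    config: AssemblyConfig | None = None,
) -> tuple[list[BackboneModel], list[StageReport]]:
    """Build full-length backbones for a blueprint in three stages.

    Stage 1 builds E1+L1+H1 (with L1 torsions taken from the motif when
    one is supplied, and the final model rigidly superposed back onto the
    motif coordinates); stage 2 appends L2+E2+L3+E3 and requires the
    E2/E3 hairpin to pair and E2 to sit against E1; stage 3 appends
    L4+H2+L5+E4.  Clash filtering applies at every stage; survivors of
    stage 3 must additionally pass the compactness/cavity filter.

    Returns the surviving models plus one StageReport per stage (always
    three, in order).  Zero survivors yields an empty list, never an
    exception.
    """
    cfg = config or AssemblyConfig()
    rng = np.random.default_rng(rng_seed)
    ranges = _segment_ranges(bp)
    segs = {s.element_id: s for s in bp.segments}

    if motif is not None and segs["L1"].length != len(motif.residues):
        raise InvalidInputError(
            f"motif length {len(motif.residues)} does not fit loop slot L1 "
            f"of length {segs['L1'].length}")
    motif_torsions = _motif_torsions(motif) if motif is not None else None

    reports = [StageReport(i + 1, _STAGE_ELEMENTS[i]) for i in range(3)]

    def torsions_for(element_ids, rng) -> list[TorsionTriple]:
        out = []
        for eid in element_ids:
            if eid == "L1" and motif_torsions is not None:
                out.extend(motif_torsions)
            else:
                out.extend(sample_torsions_for_segment(
                    segs[eid], rng, sigma_scale=cfg.sigma_scale))
        return out

    # stage 1: E1 + L1 + H1 (clash filter only)
    stage1: list[list[TorsionTriple]] = []
    for _ in range(n_tries_per_stage):
        reports[0].generated += 1
        torsions = torsions_for(_STAGE_ELEMENTS[0], rng)
        model = build_chain_from_torsions(torsions)
        if check_clashes(model, cfg.clash_min_distance) > 0:
            reports[0].failed_clash += 1
            continue
        reports[0].passed += 1
        if len(stage1) < cfg.max_carryover:
            stage1.append(torsions)

    # stage 2: + L2 + E2 + L3 + E3 (hairpin paired, E2 closing against E1);
    # the try budget is spread round-robin over the carried prefixes
    stage2: list[list[TorsionTriple]] = []
    for t in range(n_tries_per_stage if stage1 else 0):
        base = stage1[t % len(stage1)]
        reports[1].generated += 1
        torsions = base + torsions_for(_STAGE_ELEMENTS[1], rng)
        model = build_chain_from_torsions(torsions)
        if check_clashes(model, cfg.clash_min_distance) > 0:
            reports[1].failed_clash += 1
            continue
        hairpin = strand_pairing_contacts(
            model, ranges["E2"], ranges["E3"], cfg.pairing_max_no_distance)
        if (hairpin < cfg.pairing_min_contacts
                or not _sheet_closure_ok(model, ranges["E1"], ranges["E2"], cfg)):
            reports[1].failed_pairing += 1
            continue
        reports[1].passed += 1
        if len(stage2) < cfg.max_carryover:
            stage2.append(torsions)

    # stage 3: + L4 + H2 + L5 + E4, then compactness/cavity
    survivors: list[BackboneModel] = []
    for t in range(n_tries_per_stage if stage2 else 0):
        base = stage2[t % len(stage2)]
        reports[2].generated += 1
        torsions = base + torsions_for(_STAGE_ELEMENTS[2], rng)
        model = build_chain_from_torsions(torsions)
        if check_clashes(model, cfg.clash_min_distance) > 0:
            reports[2].failed_clash += 1
            continue
        ok, metrics = compactness_and_cavity_filter(
            model, cfg.rg_max, cfg.cavity_volume_max)
        if not ok:
            if metrics["radius_of_gyration"] > metrics["rg_max"]:
                reports[2].failed_compactness += 1
            else:
                reports[2].failed_cavity += 1
            continue
        reports[2].passed += 1
        model.provenance.update({
            "blueprint_key": bp.key(), "seed": rng_seed,
            "stage_metrics": metrics,
        })
        if motif is not None:
            model = _pin_motif(model, motif, ranges["L1"])
        survivors.append(model)

    return survivors, reports


def _pin_motif(model: BackboneModel, motif, loop_range: tuple[int, int]) -> BackboneModel:
    """Rigidly move the whole model so its L1 residues coincide with the
    motif's stored coordinates (the motif's internal geometry was already
    enforced through its torsions)."""
    from .grafting import kabsch_superpose
    lo, hi = loop_range
    moving = np.concatenate([model.residues[i].coords[:3] for i in range(lo, hi)])
    fixed = np.concatenate([r.coords[:3] for r in motif.residues])
    rot, trans, _ = kabsch_superpose(moving, fixed)
    out = model.transformed(rot, trans)
    for i, mres in zip(range(lo, hi), motif.residues):
        out.residues[i].aa = mres.aa
    return out
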