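"""Desk-scale interface metrics for ranking design candidates.

Binding-energy and contact-surface ranking metrics are computed as
geometric proxies: a Shrake–Rupley solvent-accessible surface area
(SASA), buried interface area, a class-weighted contact pseudo-energy
(hydrophobic packing and salt bridges favourable, like charges
penalised), and a contact surface restricted to tightly packed atom
pairs.  Designs are backbone-only, so chemistry enters through
per-residue pseudo-atom classes assigned from the sequence letter at
the CA position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .backbone import BackboneModel
from .errors import InvalidInputError

__all__ = [
    "ATOM_CLASSES",
    "RESIDUE_CLASS",
    "VDW_RADII",
    "PseudoTarget",
    "ScoreCard",
    "sphere_points",
    "sasa",
    "interface_buried_area",
    "contact_and_ddg_proxy",
    "rank_designs",
]

ATOM_CLASSES = ("hydrophobic", "donor", "acceptor", "positive", "negative")

#: Crude one-letter-code -> interaction class map for backbone-only designs.
RESIDUE_CLASS = {
    "R": "positive", "K": "positive", "H": "positive",
    "D": "negative", "E": "negative",
    "S": "donor", "T": "donor", "N": "donor", "Q": "donor", "Y": "donor",
    "A": "hydrophobic", "V": "hydrophobic", "L": "hydrophobic",
    "I": "hydrophobic", "M": "hydrophobic", "F": "hydrophobic",
    "W": "hydrophobic", "P": "hydrophobic", "G": "hydrophobic",
    "C": "hydrophobic",
}

#: Heavy-atom van der Waals radii (Å) used for SASA.
VDW_RADII = {"N": 1.55, "C": 1.70, "CA": 1.70, "O": 1.52}

#: Pairwise class-compatibility weights of the contact pseudo-energy.
_PAIR_WEIGHTS = {
    frozenset(["hydrophobic"]): -1.0,
    frozenset(["donor", "acceptor"]): -1.5,
    frozenset(["positive"]): 2.0,
    frozenset(["negative"]): 2.0,
    frozenset(["positive", "negative"]): -2.0,
}


def pair_weight(class_a: str, class_b: str) -> float:
    return _PAIR_WEIGHTS.get(frozenset([class_a, class_b]), 0.0)


@dataclass
class PseudoTarget:
    """A minimal stand-in for a receptor binding site.

    ``atoms`` is a DataFrame with columns x, y, z, radius, cls; pocket
    annotations name functional groups of atoms (e.g. the charged
    RGD-anchor pair and a hydrophobic pocket).
    """

    atoms: pd.DataFrame
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"x", "y", "z", "radius", "cls"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise InvalidInputError(f"pseudo-target atoms missing columns {sorted(missing)}")
        if len(self.atoms) < 1:
            raise InvalidInputError("pseudo-target needs at least one atom")
        radii = self.atoms["radius"].to_numpy(float)
        if ((radii < 1.0) | (radii > 2.5)).any():
            raise InvalidInputError("pseudo-target radii must lie in [1.0, 2.5] Å")
        bad = set(self.atoms["cls"]) - set(ATOM_CLASSES)
        if bad:
            raise InvalidInputError(f"unknown atom classes {sorted(bad)}")

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    @property
    def radii(self) -> np.ndarray:
        return self.atoms["radius"].to_numpy(float)

    @property
    def classes(self) -> list[str]:
        return list(self.atoms["cls"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"atoms": self.atoms.to_dict(orient="records"),
                       "annotations": self.annotations}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PseudoTarget":
        with open(path) as fh:
            d = json.load(fh)
        return cls(pd.DataFrame(d["atoms"]), d.get("annotations", {}))


@dataclass
class ScoreCard:
    """Interface metrics of one design against the target."""

    design_id: str
    ddg_proxy: float
    sasa_total: float
    interface_buried_area: float
    contact_surface: float
    clash_count: int
    passes: bool

    def to_dict(self) -> dict:
        return dict(design_id=self.design_id, ddg_proxy=self.ddg_proxy,
                    sasa_total=self.sasa_total,
                    interface_buried_area=self.interface_buried_area,
                    contact_surface=self.contact_surface,
                    clash_count=self.clash_count, passes=self.passes)


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake–Rupley)

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(coords: np.ndarray, radii: np.ndarray, probe_radius: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å^2).

    Each atom's sphere is inflated by the probe radius and sampled with
    ``n_points`` quasi-uniform points; a point contributes area when it
    lies outside every other inflated sphere.  Coincident atoms are
    handled (the duplicate simply occludes).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if n_points < 92:
        raise InvalidInputError("n_points must be at least 92")
    if (radii <= 0).any():
        raise InvalidInputError("atom radii must be positive")
    n_atoms = len(coords)
    inflated = radii + probe_radius
    unit = sphere_points(n_points)
    areas = np.empty(n_atoms)
    # neighbour prefilter
    d = cdist(coords, coords)
    for i in range(n_atoms):
        neighbours = np.where((d[i] < inflated[i] + inflated.max()) &
                              (np.arange(n_atoms) != i))[0]
        pts = coords[i] + inflated[i] * unit
        if len(neighbours):
            dist2 = cdist(pts, coords[neighbours], "sqeuclidean")
            # a point on the boundary of another inflated sphere counts as
            # buried, so coincident duplicate atoms fully occlude each other
            limit = (inflated[neighbours] ** 2)[None, :] * (1 + 1e-12) + 1e-12
            buried = (dist2 <= limit).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * inflated[i] ** 2 * frac
    return areas


def interface_buried_area(coords_a: np.ndarray, radii_a: np.ndarray,
                          coords_b: np.ndarray, radii_b: np.ndarray,
                          probe_radius: float = 1.4, n_points: int = 960) -> float:
    """Buried surface area SASA(A) + SASA(B) − SASA(A∪B), clamped at 0."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise InvalidInputError("both interface parts must be nonempty")
    a = sasa(coords_a, radii_a, probe_radius, n_points).sum()
    b = sasa(coords_b, radii_b, probe_radius, n_points).sum()
    ab = sasa(np.concatenate([coords_a, coords_b]),
              np.concatenate([radii_a, radii_b]), probe_radius, n_points).sum()
    return max(0.0, float(a + b - ab))


# ---------------------------------------------------------------------------
# contact pseudo-energy

def _design_atoms(design: BackboneModel):
    """Backbone atoms with radii; CA atoms carry the residue's class."""
    coords = design.coords
    n = len(design)
    radii = np.tile([VDW_RADII["N"], VDW_RADII["CA"], VDW_RADII["C"],
                     VDW_RADII["O"]], n)
    ca_coords = design.ca_coords
    ca_classes = [RESIDUE_CLASS.get(r.aa, "hydrophobic") for r in design.residues]
    return coords, radii, ca_coords, ca_classes


def _distance_kernel(d: np.ndarray) -> np.ndarray:
    """1 at ≤3.5 Å, linear decay to 0 at 5 Å, 0 beyond."""
    return np.clip((5.0 - d) / 1.5, 0.0, 1.0) * (d <= 5.0)


def contact_and_ddg_proxy(
    design: BackboneModel,
    target: PseudoTarget,
    clash_min_distance: float = 2.8,
    probe_radius: float = 1.4,
    n_points: int = 960,
    contact_gap: float = 1.5,
    design_id: str | None = None,
) -> ScoreCard:
    """Score one design pose against the target.

    ``ddg_proxy`` sums class-compatibility weights times a distance
    kernel over cross-interface pairs within 5 Å (more negative is
    better).  ``contact_surface`` is the buried area restricted to atoms
    with a cross-interface gap (surface-to-surface distance) of at most
    ``contact_gap``.  Cross-interface clashes flag the card as failing;
    the energy is still reported.
    """
    coords, radii, ca_coords, ca_classes = _design_atoms(design)
    t_coords, t_radii, t_classes = target.coords, target.radii, target.classes

    d_ca = cdist(ca_coords, t_coords)
    kern = _distance_kernel(d_ca)
    weights = np.array([[pair_weight(ca, tc) for tc in t_classes]
                        for ca in ca_classes])
    ddg = float((weights * kern).sum())

    sasa_design = sasa(coords, radii, probe_radius, n_points)
    sasa_target = sasa(t_coords, t_radii, probe_radius, n_points)
    joint = sasa(np.concatenate([coords, t_coords]),
                 np.concatenate([radii, t_radii]), probe_radius, n_points)
    buried_per_atom = np.concatenate([sasa_design, sasa_target]) - joint
    buried = max(0.0, float(buried_per_atom.sum()))

    # contact surface: buried area of atoms in tight cross-interface contact
    d_all = cdist(coords, t_coords)
    gap = d_all - radii[:, None] - t_radii[None, :]
    tight_design = (gap <= contact_gap).any(axis=1)
    tight_target = (gap <= contact_gap).any(axis=0)
    tight = np.concatenate([tight_design, tight_target])
    contact = float(np.clip(buried_per_atom, 0.0, None)[tight].sum())
    contact = min(contact, buried)

    clash_count = int((d_all < clash_min_distance).sum())
    return ScoreCard(
        design_id=design_id or design.provenance.get("design_id", "design"),
        ddg_proxy=ddg,
        sasa_total=float(sasa_design.sum()),
        interface_buried_area=buried,
        contact_surface=contact,
        clash_count=clash_count,
        passes=clash_count == 0,
    )


def rank_designs(cards: list[ScoreCard], thresholds: dict | None = None) -> list[ScoreCard]:
    """Filter by thresholds and rank accepted designs.

    Default thresholds accept every card.  Sorting is by
    ``ddg_proxy`` ascending (most favourable first), ties broken by
    ``contact_surface`` descending, then design id — deterministic under
    input permutation.
    """
    if not cards:
        raise InvalidInputError("no score cards to rank")
    thr = {"ddg_max": np.inf, "sasa_min": 0.0, "contact_min": 0.0,
           "require_pass": False}
    thr.update(thresholds or {})
    accepted = [
        c for c in cards
        if (c.ddg_proxy <= thr["ddg_max"] and c.sasa_total >= thr["sasa_min"]
            and c.contact_surface >= thr["contact_min"]
            and (c.passes or not thr["require_pass"]))
    ]
    return sorted(accepted,
                  key=lambda c: (c.ddg_proxy, -c.contact_surface, c.design_id))
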