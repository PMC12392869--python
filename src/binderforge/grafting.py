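"""Hotspot-loop extraction and rigid-body grafting into scaffolds.

The RGD loop is carried as a :class:`MotifDefinition` — ordered backbone
coordinates plus sequence, with the first and last motif residues acting
as alignment anchors.  Grafting superposes the motif anchors onto the
first and last residues of a scaffold loop with the Kabsch algorithm and
replaces the loop; acceptance requires a small anchor closure RMSD and a
clash-free grafted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneModel, Residue, check_clashes
from .blueprint import Blueprint
from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "MotifDefinition",
    "GraftResult",
    "kabsch_superpose",
    "extract_motif_from_complex",
    "graft_motif_into_scaffold",
    "motif_to_model",
    "model_to_motif",
]


@dataclass
class MotifDefinition:
    """A loop motif: per-residue one-letter codes and 4x3 backbone coords.

    The first and last residues are the alignment anchors (their N/CA/C
    frames drive the graft superposition).
    """

    residues: list[Residue]
    source: str = "fixture"
    #: optional full per-residue torsions (defines the junction angles that
    #: coordinates of an isolated loop cannot); used when building around
    #: the motif
    torsions: list | None = None

    def __post_init__(self):
        if len(self.residues) < 3:
            raise InvalidInputError("a motif needs at least 3 residues")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def anchor_pre(self) -> np.ndarray:
        """N/CA/C coordinates of the first motif residue."""
        return self.residues[0].coords[:3]

    @property
    def anchor_post(self) -> np.ndarray:
        """N/CA/C coordinates of the last motif residue."""
        return self.residues[-1].coords[:3]

    def anchor_coords(self) -> np.ndarray:
        return np.concatenate([self.anchor_pre, self.anchor_post])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MotifDefinition":
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        residues = [Residue(r.index, r.aa, r.coords @ rot.T + t) for r in self.residues]
        return MotifDefinition(residues, self.source, self.torsions)


@dataclass
class GraftResult:
    """Outcome of one graft attempt."""

    model: BackboneModel
    closure_rmsd: float
    replaced_segment: str
    accepted: bool
    clash_count: int = 0


def motif_to_model(motif: MotifDefinition) -> BackboneModel:
    """View a motif as a standalone backbone model (shared coordinates)."""
    return BackboneModel([Residue(i + 1, r.aa, r.coords.copy())
                          for i, r in enumerate(motif.residues)])


def model_to_motif(model: BackboneModel, source: str = "fixture") -> MotifDefinition:
    return MotifDefinition([Residue(i + 1, r.aa, r.coords.copy())
                            for i, r in enumerate(model.residues)], source)


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det +1, reflections excluded) minimising the RMSD of
    ``moving @ rotation.T + translation`` against ``fixed``.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise InvalidInputError(
            f"point sets differ in shape: {moving.shape} vs {fixed.shape}")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 three-dimensional points")

    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    h = (moving - mu_m).T @ (fixed - mu_f)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:  # rank < 2: rotation not unique
        raise DegenerateGeometryError("rank-deficient point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = mu_f - rot @ mu_m
    moved = moving @ rot.T + trans
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def extract_motif_from_complex(structure, chain: str, residue_range: tuple[int, int],
                               ) -> MotifDefinition:
    """Copy a loop (closed residue interval on one chain) out of a parsed
    structure as a motif.

    ``structure`` is the chain->residue mapping produced by
    :func:`binderforge.io.read_pdb`.  Every residue in the range must
    carry N, CA and C atoms.
    """
    lo, hi = residue_range
    if chain not in structure:
        raise InvalidInputError(f"chain {chain!r} not present in structure")
    residues = []
    for resnum in range(lo, hi + 1):
        if resnum not in structure[chain]:
            raise InvalidInputError(f"residue {chain}/{resnum} missing from structure")
        res = structure[chain][resnum]
        for atom in ("N", "CA", "C"):
            if atom not in res["atoms"]:
                raise InvalidInputError(
                    f"residue {chain}/{resnum} lacks backbone atom {atom}")
        coords = np.stack([
            res["atoms"].get(a, res["atoms"]["C"] + np.array([0.0, 0.0, 1.231]))
            for a in ("N", "CA", "C", "O")
        ])
        residues.append(Residue(resnum, res["aa"], coords))
    return MotifDefinition(
        residues, source=f"extracted(chain={chain},range={lo}-{hi})")


def _loop_range(scaffold: BackboneModel, bp: Blueprint, target_loop: str) -> tuple[int, int]:
    pos = 0
    for seg in bp.segments:
        if seg.element_id == target_loop:
            return pos, pos + seg.length
        pos += seg.length
    raise InvalidInputError(f"blueprint has no loop {target_loop!r}")


def graft_motif_into_scaffold(
    scaffold: BackboneModel,
    motif: MotifDefinition,
    target_loop: str | tuple[int, int],
    blueprint: Blueprint | None = None,
    closure_threshold: float = 0.75,
    clash_min_distance: float = 2.8,
) -> GraftResult:
    """Replace a scaffold loop with a rigidly superposed motif.

    The motif's first/last residue N,CA,C frames (6 atoms) are Kabsch-fit
    onto the scaffold loop's first/last residues; the transformed motif
    replaces the loop.  ``target_loop`` is an element id (with
    ``blueprint`` supplied) or an explicit half-open 0-based residue
    range.  Accepted iff the anchor closure RMSD is at most
    ``closure_threshold`` and the grafted model is clash-free.
    """
    if isinstance(target_loop, str):
        if blueprint is None:
            raise InvalidInputError("element-id loop lookup requires a blueprint")
        lo, hi = _loop_range(scaffold, blueprint, target_loop)
        loop_name = target_loop
    else:
        lo, hi = target_loop
        loop_name = f"{lo}-{hi}"
    loop_len = hi - lo
    if abs(loop_len - len(motif.residues)) > 2:
        raise InvalidInputError(
            f"motif length {len(motif.residues)} too far from loop length {loop_len}")

    fixed = np.concatenate([scaffold.residues[lo].coords[:3],
                            scaffold.residues[hi - 1].coords[:3]])
    rot, trans, closure_rmsd = kabsch_superpose(motif.anchor_coords(), fixed)
    placed = motif.transformed(rot, trans)

    residues = (
        [Residue(r.index, r.aa, r.coords.copy()) for r in scaffold.residues[:lo]]
        + [Residue(0, r.aa, r.coords.copy()) for r in placed.residues]
        + [Residue(r.index, r.aa, r.coords.copy()) for r in scaffold.residues[hi:]]
    )
    for i, r in enumerate(residues):
        r.index = i + 1
    grafted = BackboneModel(residues, dict(scaffold.provenance))
    grafted.provenance["grafted_loop"] = loop_name

    clashes = check_clashes(grafted, clash_min_distance)
    accepted = (closure_rmsd <= closure_threshold) and clashes == 0
    return GraftResult(grafted, closure_rmsd, loop_name, accepted, clashes)
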