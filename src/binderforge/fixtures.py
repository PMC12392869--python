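"""Synthetic inputs for every pipeline stage — nothing is downloaded.

The fixtures emulate, at desk scale, the data a binder-design campaign
consumes: a fold-topology occurrence survey, an idealized RGD loop
motif, a pseudo receptor binding site, sort-seq count tables, and
binding-assay curves.  Everything regenerates deterministically from a
seed.

The topology survey deserves a note: its most frequent options are not
arbitrary.  Loop ABEGO strings and helix lengths were selected so that a
chain built at the per-class mean torsions closes into a compact
ferredoxin-like arrangement (hairpin strands pairing, E2 returning
against E1) — which is exactly the property that makes real loop/length
combinations over-represented in fold surveys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import CLASS_TORSION_MEANS, build_chain_from_torsions
from .binding import simulate_1to1_trace, simulate_competition, simulate_dose_response
from .blueprint import TopologyStats, TorsionTriple
from .errors import ConfigurationError, InvalidInputError
from .grafting import MotifDefinition, model_to_motif
from .scoring import PseudoTarget
from .sortseq import GateInfo, SortSeqCounts

__all__ = [
    "FixtureManifest",
    "make_topology_stats",
    "make_idealized_motif",
    "make_pseudo_target",
    "default_gates",
    "simulate_sortseq_counts",
    "simulate_binding_data",
    "RGD_MOTIF_SEQUENCE",
    "RGD_MOTIF_ABEGO",
]

#: NN-C1 loop-1 sequence presented by the idealized motif fixture.
RGD_MOTIF_SEQUENCE = "HRGDFP"
#: Torsion-bin string of the idealized motif (fold-closing L1 geometry).
RGD_MOTIF_ABEGO = "GGBAEE"


@dataclass
class FixtureManifest:
    """Record of how a fixture set was generated, for byte-exact replay."""

    name: str
    parameters: dict
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add_file(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[str(path)] = digest

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "parameters": self.parameters,
                       "files": self.files}, fh, indent=1, sort_keys=True)

    def verify(self) -> bool:
        return all(
            hashlib.sha256(Path(p).read_bytes()).hexdigest() == digest
            for p, digest in self.files.items())


# ---------------------------------------------------------------------------
# topology survey

# Most-frequent options first.  The leading loop strings/helix lengths
# produce a closed ferredoxin arrangement at mean torsions (see module
# docstring); the remainder are plausible alternatives.
_LOOP_OPTIONS = {
    "L1": [RGD_MOTIF_ABEGO, "BAGAAE", "AEBGAE", "BBGBBE", "EGGAGE", "GAAAAE"],
    "L2": ["EA", "GG", "AB", "BA", "GB", "EG"],
    "L3": ["GG", "EA", "GA", "AB", "BG", "AA"],
    "L4": ["GB", "BA", "GG", "EA", "AG", "BB"],
    "L5": ["GA", "GG", "BA", "AB", "EG", "AE"],
}
_HELIX_OPTIONS = {"H1": [10, 11, 12, 13, 14], "H2": [10, 11, 12, 13, 14]}
_SHEET_OPTIONS = ["2-1-3-4:anti", "1-2-3-4:anti", "2-1-4-3:anti",
                  "3-1-2-4:mixed", "2-3-1-4:mixed", "1-3-2-4:mixed"]
_BASE_COUNTS = [340, 215, 130, 85, 55, 30]


def make_topology_stats(seed: int = 0) -> TopologyStats:
    """A synthetic fold-topology occurrence table.

    Counts follow a fixed frequency profile with a small seed-dependent
    jitter that never reorders options, so every seed yields a distinct
    but equally usable survey (≥6 ABEGO strings per loop, ≥5 lengths per
    helix, ≥6 sheet combinations).
    """
    rng = np.random.default_rng(seed)

    def jittered_counts(n: int) -> list[int]:
        # jitter < half the smallest gap between base counts: order is stable
        return [int(c + rng.integers(0, 12)) for c in _BASE_COUNTS[:n]]

    loops = {
        loop: dict(zip(opts, jittered_counts(len(opts))))
        for loop, opts in _LOOP_OPTIONS.items()
    }
    helices = {
        helix: dict(zip(opts, jittered_counts(len(opts))))
        for helix, opts in _HELIX_OPTIONS.items()
    }
    sheets = dict(zip(_SHEET_OPTIONS, jittered_counts(len(_SHEET_OPTIONS))))
    return TopologyStats(loops, helices, sheets,
                         strand_length_defaults={"E1": 5, "E2": 5, "E3": 5, "E4": 5})


# ---------------------------------------------------------------------------
# idealized RGD motif

def make_idealized_motif() -> MotifDefinition:
    """The 6-residue RGD loop (H-R-G-D-F-P) built from fixed torsions.

    Torsions sit at the per-class means of the fold-closing ABEGO string,
    so a scaffold whose L1 was sampled from the same string accepts this
    motif with a small closure RMSD.  The full torsion list (including
    the junction angles) is stored on the motif.
    """
    torsions = [TorsionTriple(*CLASS_TORSION_MEANS[letter])
                for letter in RGD_MOTIF_ABEGO]
    model = build_chain_from_torsions(torsions, sequence=RGD_MOTIF_SEQUENCE)
    motif = model_to_motif(model, source="fixture")
    motif.torsions = torsions
    return motif


# ---------------------------------------------------------------------------
# pseudo receptor site

def make_pseudo_target(seed: int = 0) -> PseudoTarget:
    """A minimal binding-groove stand-in keyed to the idealized motif.

    One negative (carboxylate-like) anchor faces the motif's Arg, one
    positive (cation-like) anchor faces the Asp — the anchors sit 6–9 Å
    apart — and a three-atom hydrophobic pocket sits under the Phe.  A
    motif docked in its fixture coordinates therefore scores a negative
    contact pseudo-energy.
    """
    rng = np.random.default_rng(seed)
    motif = make_idealized_motif()
    ca = {aa_pos: motif.residues[i].atom("CA")
          for i, aa_pos in enumerate(RGD_MOTIF_SEQUENCE)}
    centroid = np.mean([r.atom("CA") for r in motif.residues], axis=0)

    # a common outward normal keeps the anchor pair at the Arg/Asp CA
    # separation (≈6.7 Å, inside the 6–9 Å groove geometry)
    normal = 0.5 * (ca["R"] + ca["D"]) - centroid
    normal /= np.linalg.norm(normal)

    def offset(point, distance, direction):
        return point + distance * direction + rng.normal(0, 0.1, 3)

    rows = [
        {"name": "anchor_neg", "cls": "negative", "radius": 1.52,
         "xyz": offset(ca["R"], 3.2, normal)},
        {"name": "anchor_pos", "cls": "positive", "radius": 1.7,
         "xyz": offset(ca["D"], 3.2, normal)},
    ]
    pocket_dir = ca["F"] - centroid
    pocket_dir /= np.linalg.norm(pocket_dir)
    pocket_center = offset(ca["F"], 3.6, pocket_dir)
    for k in range(3):
        rows.append({"name": f"pocket_{k}", "cls": "hydrophobic", "radius": 1.7,
                     "xyz": pocket_center + rng.normal(0, 0.8, 3)})
    atoms = pd.DataFrame(
        [{"x": r["xyz"][0], "y": r["xyz"][1], "z": r["xyz"][2],
          "radius": r["radius"], "cls": r["cls"], "name": r["name"]}
         for r in rows])
    target = PseudoTarget(atoms, annotations={
        "RGD-anchor pair": ["anchor_neg", "anchor_pos"],
        "hydrophobic pocket": ["pocket_0", "pocket_1", "pocket_2"],
    })
    gap = float(np.linalg.norm(rows[0]["xyz"] - rows[1]["xyz"]))
    if not 6.0 <= gap <= 9.0:
        raise ConfigurationError(
            f"anchor pair separation {gap:.2f} Å outside 6-9 Å")
    return target


# ---------------------------------------------------------------------------
# sort-seq counts

def default_gates(target: str = "a5b1",
                  concentrations_nM=(0.1, 1.0, 10.0, 100.0, 1000.0)) -> list[GateInfo]:
    """One sorting gate per titration concentration (a single round)."""
    return [GateInfo(f"{target}_c{i}", 1, target, float(c))
            for i, c in enumerate(concentrations_nM)]


def simulate_sortseq_counts(
    true_kds_nM: dict[str, float],
    gates: list[GateInfo],
    depth: int = 100_000,
    seed: int = 0,
    noiseless: bool = False,
) -> SortSeqCounts:
    """Forward-simulate FACS sort-seq counts.

    The reference pool is uniform over variants; each gate collects
    cells with probability proportional to receptor occupancy
    c/(c + K_D), and reads are multinomial draws of the given depth
    (``noiseless=True`` returns the expectation counts instead).
    """
    if depth <= 0:
        raise InvalidInputError("read depth must be positive")
    if len({g.concentration_nM for g in gates}) < 2:
        raise InvalidInputError("need gates at two or more concentrations")
    rng = np.random.default_rng(seed)
    variants = list(true_kds_nM)
    kds = np.array([true_kds_nM[v] for v in variants], float)
    v = len(variants)
    reference = pd.Series(np.full(v, depth / v), index=variants)
    counts = {}
    for gate in gates:
        occ = gate.concentration_nM / (gate.concentration_nM + kds)
        p = occ / occ.sum()
        counts[gate.gate_id] = (depth * p if noiseless
                                else rng.multinomial(depth, p).astype(float))
    return SortSeqCounts(pd.DataFrame(counts, index=variants), reference,
                         {g.gate_id: g for g in gates})


# ---------------------------------------------------------------------------
# binding-assay tables

def simulate_binding_data(kind: str, params: dict | None = None,
                          noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Tidy binding-assay tables for the fitting module.

    ``kind='bli'``: 1:1 kinetic traces (columns series_id, phase, time_s,
    response, conc_nM); ``kind='dose'``: a saturation titration (conc_nM,
    mfi); ``kind='competition'``: per-competitor descending curves
    (competitor, conc_nM, mfi).  Defaults reproduce a subnanomolar
    binder: BLI k_on 1e6 /M/s, k_off 3.1e-4 /s (K_D 0.31 nM); on-cell
    K_D 1.9 nM; competitors at 0.9/612/150,000 nM against 5 nM labeled
    ligand.
    """
    params = dict(params or {})
    if kind == "bli":
        kon = params.pop("kon", 1e6)
        koff = params.pop("koff", 3.1e-4)
        rmax = params.pop("rmax", 1.2)
        concs = params.pop("concentrations_nM", (0.25, 0.5, 1.0, 2.0, 8.0))
        t_assoc = params.pop("association_time_s", 600.0)
        t_dissoc = params.pop("dissociation_time_s", 1200.0)
        rows = []
        for i, c in enumerate(concs):
            assoc, dissoc = simulate_1to1_trace(
                kon, koff, rmax, c * 1e-9, t_assoc, t_dissoc,
                noise_sd=noise, seed=seed + i, series_id=f"c{i}")
            for tr in (assoc, dissoc):
                for t, r in zip(tr.time_s, tr.response):
                    rows.append((tr.series_id, tr.phase, t, r, c))
        df = pd.DataFrame(rows, columns=["series_id", "phase", "time_s",
                                         "response", "conc_nM"])
    elif kind == "dose":
        kd = params.pop("kd_nM", 1.9)
        bg = params.pop("background", 100.0)
        mx = params.pop("maximum", 10000.0)
        concs = np.asarray(params.pop(
            "concentrations_nM", np.logspace(-2, 3, 12)), float)
        mfi = simulate_dose_response(kd, bg, mx, concs, noise_sd=noise, seed=seed)
        df = pd.DataFrame({"conc_nM": concs, "mfi": mfi})
    elif kind == "competition":
        kds = params.pop("competitor_kds_nM",
                         {"NN-C1": 0.9, "FN": 612.0, "RGD-peptide": 150_000.0})
        c_l = params.pop("labeled_conc_nM", 5.0)
        kd_l = params.pop("labeled_kd_nM", 1.9)
        mx = params.pop("shared_max", 10000.0)
        mn = params.pop("shared_min", 100.0)
        concs = np.asarray(params.pop(
            "concentrations_nM", np.logspace(-2, 7, 16)), float)
        curves = simulate_competition(kds, c_l, kd_l, mx, mn, concs,
                                      noise_sd=noise, seed=seed)
        rows = [(name, c, y) for name, (cs, ys) in sorted(curves.items())
                for c, y in zip(cs, ys)]
        df = pd.DataFrame(rows, columns=["competitor", "conc_nM", "mfi"])
    else:
        raise ConfigurationError(f"unknown simulation kind {kind!r}")
    if params:
        raise ConfigurationError(f"unused parameters for kind {kind!r}: "
                                 f"{sorted(params)}")
    return df
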