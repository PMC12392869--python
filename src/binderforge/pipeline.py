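"""End-to-end design pipeline: survey → blueprints → backbones → grafts → ranking."""

from __future__ import annotations

from dataclasses import dataclass

from .backbone import AssemblyConfig, BackboneModel, StageReport, assemble_stagewise
from .blueprint import Blueprint, enumerate_blueprints, rank_and_select_blueprints
import numpy as np

from .fixtures import make_idealized_motif, make_pseudo_target, make_topology_stats
from .grafting import GraftResult, graft_motif_into_scaffold, kabsch_superpose
from .scoring import ScoreCard, contact_and_ddg_proxy, rank_designs

__all__ = ["PipelineResult", "run_design_pipeline"]


@dataclass
class PipelineResult:
    blueprints: list[Blueprint]
    scaffolds: list[BackboneModel]
    grafts: list[GraftResult]
    accepted: list[GraftResult]
    ranked: list[ScoreCard]
    stage_reports: list[list[StageReport]]


def run_design_pipeline(
    seed: int = 0,
    n_blueprints: int = 4,
    tries_per_stage: int = 3000,
    closure_threshold: float = 0.75,
    top_k: int = 100,
    enumerate_kwargs: dict | None = None,
    assembly_config: AssemblyConfig | None = None,
    max_scaffolds: int = 40,
) -> PipelineResult:
    """Run the full desk-scale design loop on synthetic fixtures.

    Enumerates blueprints from the synthetic topology survey, keeps the
    ``top_k`` by occurrence score, assembles backbones for the
    ``n_blueprints`` best, grafts the idealized RGD motif into loop L1
    of every surviving scaffold, scores accepted grafts against the
    pseudo receptor site, and returns everything ranked.  Deterministic
    for a given seed.
    """
    stats = make_topology_stats(seed)
    kwargs = {"n_abego_per_loop": 5, "n_lengths_per_helix": 4, "n_sheet_combos": 5}
    kwargs.update(enumerate_kwargs or {})
    blueprints = rank_and_select_blueprints(
        enumerate_blueprints(stats, **kwargs), top_k)

    motif = make_idealized_motif()
    target = make_pseudo_target(seed)

    scaffolds: list[BackboneModel] = []
    grafts: list[GraftResult] = []
    reports: list[list[StageReport]] = []
    # unique segment layouts among the leading blueprints (sheet id does not
    # change geometry, so skip duplicates)
    seen_layouts: set[str] = set()
    chosen: list[Blueprint] = []
    for bp in blueprints:
        layout = "|".join(s.as_text() for s in bp.segments)
        if layout not in seen_layouts:
            seen_layouts.add(layout)
            chosen.append(bp)
        if len(chosen) >= n_blueprints:
            break

    for k, bp in enumerate(chosen):
        survivors, rep = assemble_stagewise(
            bp, motif=None, n_tries_per_stage=tries_per_stage,
            rng_seed=seed + 1000 * k, config=assembly_config)
        reports.append(rep)
        for j, scaffold in enumerate(survivors):
            if len(scaffolds) >= max_scaffolds:
                break
            scaffold.provenance["design_id"] = f"bp{k}_s{j}"
            scaffolds.append(scaffold)
            grafts.append(graft_motif_into_scaffold(
                scaffold, motif, "L1", blueprint=bp,
                closure_threshold=closure_threshold))

    accepted = [g for g in grafts if g.accepted]

    # dock each accepted graft into the target frame by superposing its
    # grafted loop onto the motif fixture coordinates the pseudo-site wraps
    motif_fixed = np.concatenate([r.coords[:3] for r in motif.residues])
    l1_start = next(i for i, s in enumerate(chosen[0].segments)
                    if s.element_id == "L1")
    loop_offset = sum(s.length for s in chosen[0].segments[:l1_start])
    cards = []
    for g in accepted:
        loop = g.model.residues[loop_offset:loop_offset + len(motif.residues)]
        moving = np.concatenate([r.coords[:3] for r in loop])
        rot, trans, _ = kabsch_superpose(moving, motif_fixed)
        docked = g.model.transformed(rot, trans)
        cards.append(contact_and_ddg_proxy(
            docked, target,
            design_id=g.model.provenance.get("design_id", "design") + "_graft"))
    ranked = rank_designs(cards) if cards else []
    return PipelineResult(blueprints, scaffolds, grafts, accepted, ranked, reports)
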