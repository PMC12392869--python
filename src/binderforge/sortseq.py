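"""Sort-seq screening analytics: enrichment, K_D estimation, SSM, libraries.

A yeast-display library is sorted by FACS at several ligand
concentrations; deep sequencing of the pre-sort pool and each sorted
gate yields per-variant read counts.  Assuming cells are collected in
proportion to receptor occupancy c/(c+K_D), per-variant dissociation
constants are recovered by maximum likelihood across gates.  The module
also computes positional Shannon entropies from site-saturation
mutagenesis (SSM) ΔlogK_D matrices, classifies variant specificity
between two targets, and enumerates combination libraries of beneficial
substitutions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .errors import ConfigurationError, IdentifiabilityError, InvalidInputError

__all__ = [
    "GateInfo",
    "SortSeqCounts",
    "VariantAffinity",
    "SSMMatrix",
    "enrichment_ratios",
    "estimate_kd_from_sorts",
    "ssm_entropy_profile",
    "classify_specificity",
    "build_combination_library",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GateInfo:
    """One FACS gate: sort round, target, ligand concentration, yield."""

    gate_id: str
    round: int
    target: str  # e.g. "a5b1" or "avb3"
    concentration_nM: float
    fraction_collected: float = 1.0

    def __post_init__(self):
        if self.concentration_nM <= 0:
            raise InvalidInputError("gate concentration must be positive")
        if not 0 < self.fraction_collected <= 1:
            raise InvalidInputError("fraction_collected must lie in (0, 1]")


@dataclass
class SortSeqCounts:
    """Read counts of a sorted library.

    ``counts`` is a variant × gate DataFrame (index: variant id, columns:
    gate ids); ``reference`` holds the pre-sort counts; ``gates`` maps
    gate id to :class:`GateInfo`; ``sequences`` optionally maps variant
    id to its amino-acid sequence.
    """

    counts: pd.DataFrame
    reference: pd.Series
    gates: dict[str, GateInfo]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any() or (self.reference < 0).any():
            raise InvalidInputError("read counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.gates)
        if missing:
            raise ConfigurationError(f"gates missing from manifest: {sorted(missing)}")
        if (self.counts.sum(axis=0) <= 0).any():
            raise InvalidInputError("each gate needs a positive total read count")
        self.reference = self.reference.reindex(self.counts.index).fillna(0.0)

    def gates_for_target(self, target: str) -> list[str]:
        return [g for g in self.counts.columns if self.gates[g].target == target]


@dataclass
class VariantAffinity:
    """A per-variant dissociation-constant estimate."""

    variant_id: str
    kd_nM: float
    ci_nM: tuple[float, float]
    status: str  # converged | below-range | above-range

    def __post_init__(self):
        if self.status == "converged" and not self.kd_nM > 0:
            raise InvalidInputError("converged K_D must be positive")


# ---------------------------------------------------------------------------
# enrichment

def enrichment_ratios(data: SortSeqCounts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-variant log2 enrichment of each gate over the pre-sort pool.

    log2[(c_vg + α)/(T_g + αV)] − log2[(c_v0 + α)/(T_0 + αV)] with
    pseudocount α and V variants.
    """
    ref = data.reference.to_numpy(float)
    t0 = ref.sum()
    if t0 <= 0:
        raise InvalidInputError("reference pool has no reads")
    v = len(data.counts)
    if pseudocount == 0 and (ref == 0).any():
        raise InvalidInputError(
            "variant absent from the reference pool; a pseudocount is required")
    f0 = np.log2(ref + pseudocount) - math.log2(t0 + pseudocount * v)
    out = {}
    for gate in data.counts.columns:
        c = data.counts[gate].to_numpy(float)
        fg = np.log2(c + pseudocount) - math.log2(c.sum() + pseudocount * v)
        out[gate] = fg - f0
    return pd.DataFrame(out, index=data.counts.index)


# ---------------------------------------------------------------------------
# K_D estimation

def _occupancy(conc: np.ndarray, kd: float) -> np.ndarray:
    return conc / (conc + kd)


def _poisson_nll_for_variant(kd_log10: float, counts: np.ndarray, conc: np.ndarray,
                             ref_frac: float, scale: np.ndarray) -> float:
    """Poisson negative log-likelihood of one variant's gate counts.

    Mean model: μ_g = scale_g · ref_frac · occupancy(c_g, K_D), with
    per-gate scale absorbing depth and sorting stringency.
    """
    mu = scale * ref_frac * _occupancy(conc, 10.0 ** kd_log10)
    mu = np.maximum(mu, 1e-300)
    return float((mu - counts * np.log(mu)).sum())


def _profiled_nll(kd_log10: np.ndarray, counts: np.ndarray, conc: np.ndarray,
                  ref_frac: np.ndarray, totals: np.ndarray) -> float:
    """Joint Poisson NLL over all variants with per-gate scales profiled
    out in closed form (the ML scale matches each gate's total reads)."""
    occ = _occupancy(conc[None, :], 10.0 ** kd_log10[:, None])
    expected = (ref_frac[:, None] * occ).sum(axis=0)
    scale = totals / np.maximum(expected, 1e-300)
    mu = np.maximum(scale[None, :] * ref_frac[:, None] * occ, 1e-300)
    return float((mu - counts * np.log(mu)).sum())


def estimate_kd_from_sorts(
    data: SortSeqCounts,
    target: str | None = None,
    n_iterations: int = 60,
    boundary_factor: float = 100.0,
) -> list[VariantAffinity]:
    """Maximum-likelihood per-variant K_D from multi-concentration sorts.

    Cells are assumed collected in proportion to occupancy c/(c+K_D)
    times the variant's pre-sort frequency; gate totals are absorbed by a
    shared per-gate selectivity.  Estimation alternates closed-form gate
    scales with per-variant 1-D likelihood optimisation (the coordinate
    updates of the joint Poisson MLE).  Estimates pinned to the edge of
    the searched concentration window (grid min/boundary_factor to grid
    max·boundary_factor) are reported as bounds with status
    ``below-range``/``above-range``.
    """
    gate_ids = (data.gates_for_target(target) if target
                else list(data.counts.columns))
    if not gate_ids:
        raise ConfigurationError(f"no gates for target {target!r}")
    conc = np.array([data.gates[g].concentration_nM for g in gate_ids])
    if len(np.unique(conc)) < 2:
        raise IdentifiabilityError(
            "K_D estimation needs at least two distinct concentrations")

    counts = data.counts[gate_ids].to_numpy(float)  # variants × gates
    ref = data.reference.to_numpy(float)
    ref_frac = (ref + 0.5) / (ref + 0.5).sum()
    totals = counts.sum(axis=0)

    lo = math.log10(conc.min() / boundary_factor)
    hi = math.log10(conc.max() * boundary_factor)
    kd_log10 = np.full(len(counts), math.log10(np.sqrt(conc.min() * conc.max())))

    # identical count vectors must give identical estimates: deduplicate
    keys = [tuple(row) for row in counts]
    unique_rows: dict[tuple, int] = {}
    for i, k in enumerate(keys):
        unique_rows.setdefault(k, i)

    # warm start: a few rounds of coordinate updates (closed-form scales,
    # per-variant 1-D likelihood optimisation) ...
    for _ in range(min(n_iterations, 10)):
        occ = _occupancy(conc[None, :], 10.0 ** kd_log10[:, None])
        expected = (ref_frac[:, None] * occ).sum(axis=0)
        scale = totals / np.maximum(expected, 1e-300)
        for k, i in unique_rows.items():
            res = minimize_scalar(
                _poisson_nll_for_variant, bounds=(lo, hi), method="bounded",
                args=(counts[i], conc, ref_frac[i], scale),
                options={"xatol": 1e-7})
            kd_log10[i] = res.x
        for j, k in enumerate(keys):
            kd_log10[j] = kd_log10[unique_rows[k]]

    # ... then joint minimisation of the scale-profiled likelihood, which
    # the alternating scheme alone can stall short of on its scale/K_D ridge
    sol = minimize(_profiled_nll, kd_log10,
                   args=(counts, conc, ref_frac, totals),
                   method="L-BFGS-B", bounds=[(lo, hi)] * len(kd_log10),
                   options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10})
    kd_log10 = sol.x
    for j, k in enumerate(keys):
        kd_log10[j] = kd_log10[unique_rows[k]]

    occ = _occupancy(conc[None, :], 10.0 ** kd_log10[:, None])
    scale = totals / np.maximum((ref_frac[:, None] * occ).sum(axis=0), 1e-300)

    out = []
    edge = 0.05  # log10 proximity to the search boundary
    for i, vid in enumerate(data.counts.index):
        kd = 10.0 ** kd_log10[i]
        if counts[i].sum() == 0 or kd_log10[i] >= hi - edge:
            status, kd = "above-range", 10.0 ** hi
        elif kd_log10[i] <= lo + edge:
            status, kd = "below-range", 10.0 ** lo
        else:
            status = "converged"
        if status == "converged":
            # Wald interval from the profile-likelihood curvature
            h = 0.05
            f0, fp, fm = (
                _poisson_nll_for_variant(kd_log10[i] + dh, counts[i], conc,
                                         ref_frac[i], scale)
                for dh in (0.0, h, -h))
            curv = max((fp - 2 * f0 + fm) / h ** 2, 1e-9)
            se = 1.96 / math.sqrt(curv)
            ci = (10.0 ** (kd_log10[i] - se), 10.0 ** (kd_log10[i] + se))
        else:
            ci = (10.0 ** lo, 10.0 ** hi)
        out.append(VariantAffinity(str(vid), float(kd), ci, status))
    return out


# ---------------------------------------------------------------------------
# SSM analysis

@dataclass
class SSMMatrix:
    """Site-saturation mutagenesis effects: positions × 20 amino acids.

    ``dlog_kd`` holds ΔlogK_D (log10, relative to the parent residue;
    the parent cell is 0 by definition, missing cells are NaN).
    """

    dlog_kd: pd.DataFrame  # index: 1..L, columns: AMINO_ACIDS
    parent_sequence: str

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.dlog_kd.columns)
        if missing:
            raise InvalidInputError(f"SSM matrix missing amino acids {sorted(missing)}")
        if len(self.dlog_kd) != len(self.parent_sequence):
            raise InvalidInputError("SSM matrix rows must match parent length")
        for pos, aa in zip(self.dlog_kd.index, self.parent_sequence):
            parent_val = self.dlog_kd.loc[pos, aa]
            if not (pd.isna(parent_val) or abs(parent_val) < 1e-9):
                raise InvalidInputError(
                    f"parent cell at position {pos} ({aa}) must be 0")


def ssm_entropy_profile(ssm: SSMMatrix, temperature: float = 1.0) -> pd.Series:
    """Positional Shannon entropy (bits) of Boltzmann-weighted tolerances.

    Substitution weights p_a ∝ exp(−ΔlogK_D(a)/temperature); entropy
    H = −Σ p_a log2 p_a lies in [0, log2 20].  Positions with no
    observed substitution are returned as NaN (flagged absent, not 0).
    """
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    out = {}
    for pos in ssm.dlog_kd.index:
        row = ssm.dlog_kd.loc[pos].to_numpy(float)
        observed = ~np.isnan(row)
        if not observed.any():
            out[pos] = math.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            logw = np.where(observed, -row / temperature, -np.inf)
        logw -= np.nanmax(np.where(observed, logw, -np.inf))
        w = np.exp(logw, where=np.isfinite(logw), out=np.zeros_like(row))
        p = w / w.sum()
        nz = p > 0
        out[pos] = float(-(p[nz] * np.log2(p[nz])).sum())
    return pd.Series(out, name="entropy_bits")


# ---------------------------------------------------------------------------
# specificity

def classify_specificity(
    affinities_a5b1: Sequence[VariantAffinity],
    affinities_avb3: Sequence[VariantAffinity],
    fold_threshold: float = 100.0,
    kd_max_nM: float = 100.0,
) -> pd.Series:
    """Label variants specific_a5b1 / cross_reactive / nonbinder.

    A variant is specific when it binds the primary target tightly
    (K_D ≤ kd_max_nM) and the off-target K_D is at least fold_threshold
    times larger; binders failing the fold criterion are cross-reactive;
    variants out of range on the primary target are nonbinders.
    """
    a = {v.variant_id: v for v in affinities_a5b1}
    b = {v.variant_id: v for v in affinities_avb3}
    unmatched = set(a) ^ set(b)
    if unmatched:
        raise InvalidInputError(f"unmatched variant ids: {sorted(unmatched)}")
    labels = {}
    for vid, va in a.items():
        vb = b[vid]
        if va.status == "above-range":
            labels[vid] = "nonbinder"
        elif (va.kd_nM <= kd_max_nM
              and vb.kd_nM / va.kd_nM >= fold_threshold):
            labels[vid] = "specific_a5b1"
        else:
            labels[vid] = "cross_reactive"
    return pd.Series(labels, name="specificity")


# ---------------------------------------------------------------------------
# combination libraries

def build_combination_library(
    beneficial_substitutions: Sequence[tuple[int, str]],
    parent: str,
) -> list[str]:
    """All combinations of beneficial substitutions over the parent.

    ``beneficial_substitutions`` lists (1-based position, amino acid);
    several substitutions may target the same position.  The library is
    the Cartesian product of {parent residue} ∪ {substitutions} at each
    listed position — the parent sequence itself is always included.
    Substitutions identical to the parent residue are dropped with a
    warning.  Output order is deterministic (positions ascending, parent
    residue first).
    """
    options: dict[int, list[str]] = {}
    for pos, aa in beneficial_substitutions:
        if not 1 <= pos <= len(parent):
            raise InvalidInputError(f"position {pos} outside parent sequence")
        if aa not in AMINO_ACIDS:
            raise InvalidInputError(f"unknown amino acid {aa!r}")
        if aa == parent[pos - 1]:
            warnings.warn(f"substitution {pos}{aa} equals the parent residue; dropped")
            continue
        bucket = options.setdefault(pos, [])
        if aa not in bucket:
            bucket.append(aa)

    positions = sorted(options)
    choices = [[parent[p - 1]] + sorted(options[p]) for p in positions]
    library = []
    for combo in itertools.product(*choices):
        seq = list(parent)
        for pos, aa in zip(positions, combo):
            seq[pos - 1] = aa
        library.append("".join(seq))
    return library
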