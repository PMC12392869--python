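# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic fixtures do and do not emulate, and the
numerical choices a maintainer would want to know.

## Torsion bins and blueprints

Backbone conformation is coarse-grained into five ABEGO bins over
(φ, ψ, ω): `O` for cis peptides (|ω| < 90°), and for trans residues
`A` (φ<0, −75 ≤ ψ < 50 — right-handed helical), `B` (φ<0 otherwise —
extended), `G` (φ≥0, −100 < ψ ≤ 100 — left-handed helical) and `E`
(φ≥0 otherwise).  The classification is total: every finite torsion
triple maps to exactly one bin.  Angles are normalized to [−180, 180).

A blueprint fixes the ferredoxin segment order
`E1 L1 H1 L2 E2 L3 E3 L4 H2 L5 E4`, with lengths for all segments and an
ABEGO string per loop.  Enumeration takes the top-n options per factor
from a topology survey (ties on count break lexicographically) and forms
the full Cartesian product; with the defaults (5 strings/loop, 4
lengths/helix, 5 sheet arrangements) that is 250,000 blueprints.  The
joint score is the sum of log occurrence frequencies of the chosen
options, treating factors as independent — "most occurring" becomes a
naive-Bayes-style joint frequency.  Ranking is score-descending with a
lexicographic tie-break on the canonical segment text, so selection is
deterministic and idempotent; no randomness enters this module.  Sheet
arrangements are opaque identifiers (strand order + parallel/antiparallel
tag): they contribute to the score but not to geometry, because strand
pairing is enforced geometrically during assembly instead.

## Backbone construction

Chains grow residue by residue in internal coordinates (NeRF): ideal
bond lengths N–CA 1.458, CA–C 1.525, C–N 1.329 Å and angles N–CA–C
111.2°, CA–C–N 116.2°, C–N–CA 121.7°; φ/ψ/ω are the only degrees of
freedom.  Carbonyl oxygens sit 1.231 Å from C along the in-plane
bisector opposite N(i+1) (the terminal residue bisects against its own
N).  The build/measure round trip reconstructs interior torsions to
better than 1e-5° (tested at 1e-6 in unit tests, ~1e-13 in practice).

Torsion sampling is per-ABEGO-class Gaussian — A: μ=(−63, −42), σ=8°;
B: μ=(−120, 130), σ=15°; G: μ=(60, 35), σ=10°; E: μ=(120, −130), σ=15° —
with rejection until the draw re-classifies to the requested letter.
Helices sample as A, strands as B.  Cis (`O`) residues are refused
unless explicitly enabled, since nothing downstream models cis-proline
geometry.

### Staged assembly and filters

Assembly follows the three-stage schedule (E1+L1+H1; +L2+E2+L3+E3;
+L4+H2+L5+E4).  The try budget per stage is spread round-robin over up
to 16 carried prefixes, so one good stage-1 fragment can seed many
stage-2 attempts.  Filters:

- **Clash**: any two backbone atoms at sequence separation ≥ 2 residues
  closer than 2.8 Å.
- **Hairpin pairing** (stage 2): the E2/E3 hairpin must form ≥ 2
  inter-strand N···O contacts < 3.5 Å.
- **Sheet closure** (stage 2): E2 must return against E1 — minimum
  CA–CA distance < 6.5 Å with positive strand-direction dot product
  (parallel).  A hydrogen-bond-register criterion is deliberately *not*
  used here: torsion sampling without any minimization step cannot
  realize N···O registry across an intervening 10+-residue helix (the
  measured hit rate is indistinguishable from zero), whereas proximity +
  orientation passes at a workable rate and the compactness filter
  removes the frauds.  `strand_pairing_contacts` still implements the
  strict N···O criterion for callers who build with refinement.
- **Compactness** (stage 3): CA radius of gyration ≤
  1.3·(0.395·N^0.6 + 7.257) Å — the empirical folded-protein scaling
  with 30% slack for backbone-only models.
- **Cavity** (stage 3): interior void ≤ 8·N Å³ by a voxel scan (1.0 Å
  grid anchored to the model's bounding box, occupancy radius = atom
  1.7 Å + probe 1.4 Å, an empty voxel counts as cavity when occupied
  voxels enclose it along ≥ 5 of the 6 axis directions).  The budget is
  per-residue because a backbone-only model has no side chains: the
  space they would fill (≈6–7 Å³/residue in compact assemblies)
  registers as void, so a few-voxel absolute allowance would reject
  everything.  Both thresholds are configurable on `AssemblyConfig`.

Note the voxel cavity volume is exactly invariant under translation
(the grid moves with the bounding box) but only approximately under
rotation, as for any grid method; clash counts and Rg are exactly
rigid-motion invariant.

When a motif is supplied, its stored torsions replace the L1 samples and
the finished model is rigidly superposed back onto the motif
coordinates, so the motif is held fixed in space up to floating-point
error.

## Motif grafting

Kabsch superposition (SVD with reflection correction, proper rotation
guaranteed) aligns the motif's first and last residues' N/CA/C frames
(6 atoms) onto the first and last residues of the scaffold loop; the
transformed motif then replaces the loop.  Closure RMSD is the post-fit
deviation over those 6 anchor atoms; a graft is accepted at closure
≤ 0.75 Å with zero clashes.  Length mismatches up to ±2 residues are
re-indexed without loop-closure refinement.  Self-grafts close at 0 by
construction, and grafting commutes with rigid motions of the scaffold.

## Interface scoring

Designs are backbone-only, so chemistry is attached per residue: the CA
atom carries an interaction class derived from the sequence letter
(R/K/H positive, D/E negative, S/T/N/Q/Y donor, the rest hydrophobic).
The contact pseudo-energy sums, over cross-interface pairs within 5 Å, a
class-compatibility weight (hydrophobic–hydrophobic −1, donor–acceptor
−1.5, like charge +2, opposite charge −2, else 0) times a distance
kernel (1 up to 3.5 Å, linear to 0 at 5 Å).  It is exactly additive
over disjoint interface patches and rigid-motion invariant.

SASA is Shrake–Rupley: golden-spiral point sampling (960 points default,
radii N 1.55 / C 1.70 / O 1.52 Å, probe 1.4 Å); a surface point on or
inside any other inflated sphere is buried, which makes coincident
duplicate atoms fully occlude each other.  Buried interface area is
SASA(A)+SASA(B)−SASA(A∪B) clamped at zero; the contact surface restricts
the per-atom buried area to atoms with a cross-interface
surface-to-surface gap ≤ 1.5 Å, which keeps contact ≤ buried by
construction.  Finite point sampling means areas are exact under
translation but only ~1–2% reproducible under rotation; 960 vs 4000
points agree within 1%.

Ranking filters on configurable thresholds (default accept-all) and
sorts by pseudo-energy ascending, contact surface descending, design id
— deterministic under input permutation.

## Sort-seq affinity estimation

The forward model: the pre-sort pool has frequencies f_v; a gate at
ligand concentration c collects cells in proportion to occupancy
θ_v = c/(c + K_D,v); reads are multinomial over variants with
probability ∝ f_v·θ_v.  The estimator treats counts as Poisson with
mean s_g·f_v·θ_v(c_g) where the per-gate scale s_g absorbs depth and
sorting stringency; s_g has a closed-form ML solution given the K_Ds, so
the estimator minimizes the scale-profiled joint likelihood over all
log K_Ds (L-BFGS-B, warm-started by a few coordinate passes — the
coordinate scheme alone can stall on the scale/K_D ridge).  Estimates
within 0.05 log10 of the search boundary (concentration grid extended
100× both ways) are reported as `below-range`/`above-range` bounds, not
point values; identical count vectors get identical estimates by
construction.  Wald intervals come from the profile-likelihood
curvature.  The estimator is pluggable in the sense that it is a plain
function of a `SortSeqCounts`; a mean-bin style estimator can be swapped
in without touching the container.

SSM entropies weight substitutions by p_a ∝ exp(−ΔlogK_D(a)/T) (T = 1
default; T is a softness dial, not a physical temperature) and report
H = −Σ p_a log2 p_a ∈ [0, log2 20]; all-missing positions are NaN.
Specificity calls require K_D(primary) ≤ 100 nM and an off-target/primary
fold ≥ 100 (both configurable).  Combination libraries are the Cartesian
product of {parent} ∪ {substitutions} at each listed position, parent
included, warn-and-dedup on substitutions equal to the parent residue.

## Binding models

All fits are bounded least squares in log-parameter space with
multistart initialization (5 log-spaced starts, tolerances 1e-12), so
they are deterministic; exact optimizer parity with vendor software is
not a goal — parameter recovery is the contract, and round trips on
noiseless forward simulations recover inputs to well under 1%.

- 1:1 kinetics: association R(t) = R_eq(1−e^{−(k_on C+k_off)t}) with
  R_eq = R_max C/(C+K_D); dissociation decays from the model's
  association endpoint of the same series.  K_D is reported as
  k_off/k_on (an identity, not a fit).  Single-concentration data
  without dissociation is flagged, not rejected.
- Dose-response: MFI(c) = bg + (max−bg)·c/(c+K_D); standard errors from
  the covariance at the optimum; flat titrations raise an
  identifiability error.
- Competition: descending logistic MFI(x) = min + (max−min)/(1+x/EC50)
  with Hill slope fixed at 1, min/max shared across competitors and one
  EC50 each; K_D = EC50/(1 + C_L/K_D,L).  Competitors showing no
  decrease get their EC50 flagged as a lower bound.  With one competitor
  the fit coincides with a plain descending three-parameter fit.
- Exact competition: for regimes where receptor or labeled-ligand
  depletion invalidates the logistic approximation (e.g. polarization
  assays with receptor near K_D), `exact_competition_fraction_bound`
  solves the coupled ternary equilibria in closed form (trigonometric
  cubic root), verified against a numerical mass-balance solve.  It is a
  forward-model variant; the logistic fit stays the default.

## Synthetic fixtures

The fixtures emulate inputs, not experiments: the topology survey is a
fixed frequency profile with seed-jittered counts (jitter below the
smallest inter-option gap, so rankings never reorder); the leading loop
strings and helix lengths were chosen so a chain built at the class-mean
torsions closes into a ferredoxin-like arrangement — the same property
that makes real loop/length combinations over-represented in fold
surveys.  The idealized RGD motif (H-R-G-D-F-P) is built at the class
means of the fold-closing L1 string, and the pseudo receptor site is
keyed to it: a negative/positive anchor pair 6–9 Å apart facing the Arg
and Asp, plus a three-atom hydrophobic pocket under the Phe.

What the fixtures do **not** emulate: real torsion distributions (no
fragment statistics, no residue-specific Ramachandran coupling), side
chains and packing, NGS error profiles or PCR bias, sensor drift or
mass-transport artifacts in binding data.  Passing tests therefore
demonstrate the correctness and statistical behaviour of the methods
under their own models — recovery, invariances, determinism — not
performance on laboratory data.

## Problem sizes and determinism

Default test-scale sizes: 250,000 blueprints enumerated once (~15 s);
assembly at 1,500–2,500 tries/stage per blueprint (a few seconds each);
the end-to-end example (2 blueprints) finishes in ~20 s and yields tens
of scaffolds with ~50% graft acceptance.  Every stochastic entry point
takes an explicit seed (`numpy.random.default_rng`), and equal seeds
give byte-identical outputs, including written PDB files.

## Known limitations

- No sequence design or refinement: scaffolds stay poly-Gly outside the
  motif, and interface chemistry is a per-residue class, so the
  pseudo-energy separates gross complementarity only.
- The sheet-closure criterion accepts strand pairs without hydrogen-bond
  register; downstream users wanting real sheets must add minimization.
- The cavity detector's 5-of-6 ray rule flags deep crevices as cavities;
  its per-residue budget is calibrated for backbone-only models and is
  not meaningful for all-atom structures.
- The sort-seq model ignores expression variation between clones and
  assumes one round of sorting per gate; multi-round enrichment is
  summarized by gate metadata only.
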