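# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
places where the design was genuinely open.

## Units and coordinate conventions

Lengths are Å and times ns throughout; persistence-length results are
reported in nm (the unit the field quotes them in), converted on entry to
the WLC module. Temperatures are K, spring constants kcal mol⁻¹ rad⁻², with
k_B = 1.9872041×10⁻³ kcal mol⁻¹ K⁻¹ and a default simulation temperature of
310 K. Residue numbers follow the source PDB author numbering (the bead
table references subunit E/G author IDs).

PDB alternate locations are resolved by keeping the highest-occupancy
variant, ties broken by file order; hydrogens are kept when present.
Trajectory windows are half-open [start, end) on frame time so that
concatenating abutting windows never duplicates a boundary frame; a union's
nominal duration is the sum of window lengths and its frame times are
re-indexed contiguously.

## Superposition, RMSD, RMSF

The fit is the weighted Kabsch solution: SVD of the weighted covariance of
the centred coordinate sets, with the determinant-corrected composition so
the rotation is always proper. Inputs with fewer than three atoms or
(near-)collinear geometry are rejected — the optimum is not unique there.
Superposition weights default to uniform over the selected Cα atoms;
mass-weighting is an option. RMSD series fit and measure on the same atom
set (selection minus exclusion), so an excluded disordered loop influences
neither.

The average structure defaults to a single pass (align every frame to the
first, then average); iterative refinement — re-align to the running mean
until the mean shifts less than a tolerance (default 10⁻⁴ Å RMS) — is
opt-in, and non-convergence warns rather than fails. RMSF is computed after
aligning all frames to the average structure:
RMSF_i = √⟨‖r_i − ⟨r_i⟩‖²⟩. Per-residue values take the residue's Cα (mean
over its selected atoms when no Cα is selected). Whether to use all atoms
or Cα only is a free choice in the literature; Cα is the default here and
all-atom selections are expressed through the selection grammar.

### Hinge detection

No standard numeric criterion exists for "hinge", so the operationalization
is: per chain, smooth the residue RMSF with a centred moving average
(window 5 residues), threshold at the chain's 25th percentile, report
maximal runs of ≥ 4 residues below threshold, and suppress runs touching a
chain terminus (floppy ends are not pivots). All four numbers are
parameters.

A caution learned from the hinged-rod generator: under a single global
superposition the displacement node of a two-arm pivot forms one to three
beads *beside* the soft angle, not on it — the rigid fit redistributes part
of the swing into a counter-rotation whose node need not coincide with the
mechanical pivot. Detected hinge intervals should therefore be read as
"low-mobility neighbourhood of a pivot", with a bead-scale position
uncertainty; the recovery test asserts proximity (≤ 3 residues), not
containment.

## Principal component analysis

Covariance is computed on Cartesian Cα coordinates, unweighted, after
alignment to the iterative mean, with the ensemble-average (1/N frames)
denominator conventional in essential-dynamics tools; projections then have
population variance exactly equal to their eigenvalue. Eigendecomposition
uses the dense symmetric solver; eigenvalues are sorted descending with
tiny negatives (≥ −10⁻⁸ relative) floored to zero, and each eigenvector's
largest-magnitude component is made positive so outputs are deterministic
across BLAS builds. PMFs are occupancy histograms over two PC axes
(default 50×50 bins spanning the observed range ±5%), Boltzmann-inverted as
G = −ln(n/n_max) k_BT with empty bins masked rather than regularised — no
smoothing or pseudo-counts, since none is claimed for the original
surfaces. External conformations (reference crystal structures) can be
projected onto the modes to place markers on the PMF.

## Coarse-grain elasticity

The bead map is an ordered list of beads, each a set of per-chain inclusive
residue intervals; assignments must be disjoint and non-empty, and residues
inside a chain's span that no bead covers are reported (the shipped stator
table leaves E:14–15 unassigned — faithfully reproduced, not repaired).
Bead centers default to centers of mass (geometric centers optional; the
original choice is unrecorded). For n beads the chain defines n−2 bending
angles and n−3 dihedrals over consecutive beads.

Spring constants come from equipartition: k_i = k_B T/(2 σ_i²). **This k
belongs to the U = k·Δx² potential convention — it is half the U = ½k·Δx²
force constant.** Dihedral variances are computed on the unwrapped series
(cumulative ±2π correction) because the naive variance of wrapped angles is
biased near ±π; a circular-variance cross-check is exposed. Sample
variances use the n−1 denominator (negligible at trajectory scale, fixed
for determinism; frame-duplication invariance of k therefore holds to
O(1/n)). A zero (machine-level) variance is an error per coordinate, not a
silent infinity. Coordinates touching a neck-tagged bead are classed
"neck", otherwise they inherit their beads' common domain tag.

## Worm-like-chain persistence length

⟨R_ee²⟩ is the raw second moment of the end-to-end distance — the quantity
on the left of the WLC relation — not the variance about the mean; the
variance-based reading of "fluctuations of the distance" is exposed as an
option but excluded from defaults. Endpoints default to the terminal tail
beads (P6, P15) and the contour length to the time-averaged summed
consecutive bead-center distances along the tail (a fixed-axis alternative
exists). The forward map is evaluated with expm1 and, for L/L_p < 10⁻⁴,
a series branch ⟨R_ee²⟩ = L²(1 − x/3 + x²/12 − x³/60), which keeps the
near-rigid regime fully stable. Inversion brackets log L_p over
[10⁻⁹L, 10⁹L] and solves with Brent's method to ~10⁻¹² relative.
Uncertainty is a block bootstrap over frames (default block 50 frames,
1000 replicates, seeded): blocks are resampled with replacement, contour
length and ⟨R_ee²⟩ re-measured, and the relation re-inverted per replicate;
replicates that come out straighter than a rigid rod are infeasible and
dropped. For ensembles of independent chains a block length of 1 reduces
this to the ordinary bootstrap.

## Synthetic generators: what they emulate, and what not

- **Gaussian mode ensemble** — frames = ref + Σ a_i v_i + ε with
  a_i ~ N(0, λ_i) and isotropic noise ε, optionally wrapped in random
  per-frame rigid motions to exercise the alignment path. The planted
  shapes are projected out of the reference's rigid-body subspace
  (translations + infinitesimal rotations) before orthonormalisation;
  otherwise superposition silently absorbs part of the planted variance and
  no estimator could recover it. The stand-in stator geometry (`synthetic_stator`)
  is two Cα strands spanning the real subunits' residue ranges (E:3–188,
  G:21–120) so the shipped bead table applies verbatim; defaults are 9/3/1 Å²
  mode variances over a 0.1 Å noise floor at 0.5 ns/frame.
- **Discrete worm-like chain** — successive segment directions drawn from
  p(cosθ) ∝ exp(κ cosθ) with κ matched (via the Langevin function) to
  ⟨cosθ⟩ = e^(−b/L_p), azimuth uniform. The exponential correlation is
  exact, so the planted L_p needs no small-angle extrapolation; residual
  disagreement with the continuum relation is O(b/L_p). Default segment
  length is small against L_p (the recovery studies use b = 0.5 nm against
  L_p ≥ 50 nm).
- **Hinged rod** — each bending angle/dihedral sampled independently from
  its Boltzmann distribution (σ_i² = k_BT/2k_i; angles resampled into
  (0, π)), reconstructed with fixed bond lengths by the standard
  internal-coordinate embedding: bead 1 at the origin, bead 2 on +z, bead 3
  in the xz-plane. Equilibrium angles should sit ≥ 3σ from the 0/π
  boundaries or truncation biases the variance (the recovery tests use
  θ₀ = 2.0 rad).
- **Harmonic samples** — N(θ₀, k_BT/2k) draws, optionally wrapped to
  (−π, π] to exercise the unwrap path.

None of these emulate solvent, force-field anisotropy, coupling between
internal coordinates, or the real EG geometry beyond topology shape —
passing recovery tests demonstrates the estimators are correct and
unbiased under their own model assumptions, not that real trajectories
satisfy those assumptions.

## Problem sizes and determinism

Recovery studies run at desk scale chosen to put sampling error well below
the asserted tolerances: 5000 frames for PCA subspace/fraction recovery,
10⁵ samples for equipartition arithmetic, 10⁴ frames for hinged-rod
profiles, 2000 chains for WLC inversion (bootstrap scaling uses 500–8000).
Every stochastic path takes a NumPy Generator seed; fixture files round
coordinates to format precision before writing so one seed regenerates
bit-identical bytes, and pipeline reports exclude timestamps so identical
config + seed reproduces identical report bodies.

## Known limitations

- Hinge intervals are superposition-relative (see above) and depend on the
  percentile/window/run-length parameters; they are a screening tool, not a
  mechanical decomposition.
- The equipartition k assumes independent harmonic coordinates; correlated
  or anharmonic fluctuations fold into an *effective* stiffness.
- The WLC inversion is ill-conditioned as ⟨R_ee²⟩ → L² (d⟨R_ee²⟩/dL_p → 0):
  for chains much shorter than their persistence length, small errors in
  ⟨R_ee²⟩ amplify strongly in L_p — visible in the wide bootstrap bands for
  stiff, short tails.
- Selections support chain / residue-range / atom-name predicates with
  and/or/not only; no distance-based or secondary-structure selections.
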