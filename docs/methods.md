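# Methods

This note records the models implemented in `msmpath`, their assumptions,
the defaults that matter, and the design choices made where the standard
workflow leaves room.

## Markov state models

State populations evolve by the master equation P(nτ) = [T(τ)]ⁿ P(0),
with T(τ) the row-stochastic transition matrix estimated from transition
counts at lag τ. Counting is sliding-window by default (every frame pair
at offset τ contributes; uses all data) with a strided mode for strictly
independent counts; pairs never cross trajectory boundaries, since
concatenating independent runs would fabricate transitions.

Estimation is restricted to the largest strongly connected component of
the count graph (dropped states are reported); without this restriction
the stationary distribution is ill-defined. The default estimator is the
detailed-balance-constrained maximum-likelihood estimator, computed by
the standard fixed-point iteration on the symmetric flux matrix
x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j); it is the appropriate choice
for physical systems sampled at equilibrium. Plain row-normalization is
retained (`reversible=False`) and serves as the independent estimator in
validation (the Chapman–Kolmogorov reference curves use it, so model and
reference do not share an estimator). For reversible models the spectrum
is computed from the π-symmetrized matrix D^½ T D^−½ via a symmetric
eigensolver, guaranteeing a real, complete spectrum.

Implied timescales are tᵢ = −τ/ln λᵢ₊₁ in physical units
(lag frames × frame interval). λ = 1 maps to +∞; λ ≤ 0 or complex
eigenvalues have no real relaxation time at that lag and are flagged as
undefined rather than propagated as NaN. The lag-time scan reports a
plateau heuristic (successive relative change of the slowest timescale
< 10%) but never selects a lag silently — lag choice is always explicit,
with 3 ns as the conventional operating point for a single protein
domain at the 200-microstate resolution.

The Chapman–Kolmogorov test compares, per macrostate group, the staying
probability predicted by [T(τ)]ⁿ with a direct re-estimation at lag nτ,
with multinomial standard errors sqrt(p(1−p)/N) from the N counted
transitions leaving the group; points where the data run out are marked
missing, never extrapolated. The choice of a multinomial error model is a
package convention (plots of this test conventionally omit an explicit
error model).

## Statistical error model for chain-sampling checks

Tests that compare empirical state occupancies of a sampled chain with
the generating stationary distribution use the autocorrelation-corrected
multinomial variance Var(freq_i) = [π_i(1−π_i) + 2 Σ_{k≥1}(π_i(Tᵏ)_{ii} −
π_i²)]/n, computable exactly from the generating matrix. The plain
multinomial term alone underestimates the sampling error of a correlated
chain by roughly the integrated autocorrelation time and would flag
correct estimates. Where no analytic chain is available (the end-to-end
double-well recovery), the effective sample size is taken as the number
of observed interbasin transitions, and the comparison is made on the log
population ratio with σ ≈ sqrt(1/N₊ + 1/N₋) ≈ sqrt(2/N_switches).

## PCCA+

Lumping uses the inner-simplex algorithm on the first m right
eigenvectors: the first vertex is the row of the eigenvector matrix with
the largest norm; after shifting it to the origin, subsequent vertices
maximize the residual norm with previously chosen directions projected
out. Memberships are the barycentric coordinates with respect to the
vertex rows (χ = X·A with A the inverse of the vertex submatrix), clipped
at zero and renormalized; the crisp map is the row argmax. Macrostate
equilibrium probabilities are crisp sums of microstate π (a fuzzy-weighted
variant is available); the crisp-sum convention is used everywhere
results are reported.

## Transition path theory

The forward committor solves (I − T_II) q_I = T_IB·1 with q = 0 on the
source set A and 1 on the sink set B; the backward committor is 1 − q⁺
for reversible models (asserted) and otherwise solved on the
time-reversed matrix. Reactive flux f_ij = π_i q⁻_i T_ij q⁺_j (reactive
current into A and out of B is excluded), net flux f⁺ = max(0, f − fᵀ),
total flux the net current leaving A. Coarse-graining sums micro net
fluxes between lumped sets and re-antisymmetrizes; A and B must each lie
inside a single macrostate.

Pathway decomposition is greedy bottleneck removal: find the A→B path
with the largest minimum-edge capacity (widest-path search with
lowest-index tie-breaks, which makes the decomposition deterministic and
lexicographically stable), subtract its bottleneck flux along the path,
repeat. Different valid decompositions of the same network yield
different percentage splits; this one is the common convention in
coarse-grained flux analysis and is cross-checked in the tests against an
independently implemented exhaustive simple-path enumeration. Pathway
percentages are fractions of the *total* A→B flux (not of the decomposed
part only), and fluxes are reported per lag-time unit — absolute rates
require a physical time calibration that is out of scope.

## Structural metrics

Superposition is closed-form Kabsch: SVD of the 3×3 covariance with the
determinant correction, so reflections are never returned; selections
whose centered covariance has rank < 2 (collinear) are rejected because
the optimal rotation is not unique. RMSD/RMSF/Rg are mass-uniform — the
analyses operate on Cα atoms only. RMSF superposes the window frames onto
the window-mean structure (align to first, form mean, re-align once);
aligning to the first frame instead is exposed as an option since the
convention is not universal. The default analysis selection for protein
input is Cα of residues 10–124 (the structured core of the 127-residue
transthyretin monomer), configurable.

The DCCM uses full 3-D vector dot products, as the correlation definition
is written, not per-axis correlations. State-conditional maps re-align
the frame subset to its own mean before building the displacement field;
conditioning without re-alignment inherits artifacts of the global
alignment. Zero-fluctuation particles yield flagged undefined rows, not
NaN contagion. A caution that also shaped the tests: a latent mode with a
nonzero net translation is partially absorbed and redistributed by the
rigid-body fit, which induces spurious anti-correlations; planted-mode
constructions therefore use translation-free modes.

## Features and discretization

Features are all Cα–Cα pairwise distances (the "Cα distances" convention
is ambiguous between all pairs and sequential neighbours; all pairs is
used and a strided-particle subset offered for large systems). Features
are mean-centered but not variance-scaled before PCA — all columns share
Å units. The PC count defaults to the smallest number explaining ≥ 90% of
variance, capped at 10 (no standard choice exists; this rule is
reproducible and data-driven). Clustering operates in PC space by default
with a raw-distance-space option. k-means pools all trajectories for
fitting but keeps assignments per trajectory. k defaults to 200 (the
conventional microstate resolution for a protein domain); the synthetic
double-well studies use k = 50, matching their much lower intrinsic
dimensionality.

## Synthetic generators: what they emulate, and what they do not

The generators reproduce the *statistical* structure of a long
equilibrium MD ensemble whose slow dynamics are governed by a few
metastable basins: 10²–10³ particles' worth of geometry (configurable;
the standard study uses 30), frame-interval-scale fast noise, and
interbasin relaxation times 10²–10³ frame intervals. They do not emulate
force-field physics, solvent, secondary structure, or any specific
protein's fluctuation amplitudes — passing tests demonstrate that the
pipeline recovers known kinetics and thermodynamics from data of this
shape, not that any particular biomolecular conclusion is correct.

The standard double well places Gaussian wells (width 0.5) at x = ±1.5 on
a quadratic background (k = 2 kT), shallow-well depth 5.5 kT, diffusion
coefficient 1, dt = 0.01 with output stride 10. The barrier is ≈ 3 kT
above the shallow well, giving interbasin relaxation of ≈ 2×10² frame
intervals — squarely in the target regime. The `delta_kT` parameter is
the *free-energy* difference between basins: the depth offset of the
second Gaussian is calibrated by quadrature (Brent root-find on the
log-ratio of basin partition integrals) so that the Boltzmann basin
weights are exactly e^Δ : 1; a raw depth offset of Δ would be biased by
the unequal well curvatures it creates. Basin ground-truth labels are
nearest-well-center assignments.

The Euler–Maruyama integrator enforces the stability guard
dt·max|∇U|·D/kT < 0.1 × (minimum well spacing) and rejects diverging
paths naming the criterion. The embedding drives displacement along fixed
random orthonormal, translation-free modes of the template (amplitude
2 Å per latent unit) plus isotropic Gaussian noise (default σ = 0.1 Å),
which makes pairwise-distance features informative by construction; the
first PC of those features recovers the latent path with |r| > 0.99 at
default noise.

## Problem sizes

The end-to-end double-well studies use 4×10⁵ integrator steps (4×10⁴
frames after striding), 30 particles, 50 microstates, lag 10 frames, and
2 macrostates — sizes chosen so the slow mode is sampled through ≈ 10²
interbasin transitions, which bounds the statistical error of the
recovered population ratio at a few percent while the whole analysis
remains a sub-minute computation. The pipeline default configuration is
the same system; all sizes are configuration fields.

## Known limitations

- No TICA or other kinetic embeddings; PCA is the only reduction.
- No Bayesian/ensemble uncertainty on transition matrices beyond the CK
  error bars; no hidden Markov models; no milestoning.
- Secondary-structure analysis and hydrogen-bond analysis are out of
  scope; representative conformations are exported by frame index (and
  as multi-model PDB only when a topology is supplied).
- Committor and flux computations are dense linear algebra, appropriate
  for the ≤ 10³ microstates this pipeline targets.
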