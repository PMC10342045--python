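# Methods

This note documents the models, estimators, defaults, and numerical choices
behind msmflux, and what the synthetic tests do and do not establish.

## Featurization

Backbone torsions are computed with the atan2 construction
(`atan2((n₁×n₂)·û₂, n₁·n₂)` with n₁ = b₁×b₂, n₂ = b₂×b₃), which is stable
near 0°/180°; the sign follows the IUPAC convention and is cross-checked in
the tests against an independent library and a two-plane-normal oracle.
Angles live on (−180°, 180°] everywhere — a single wrap convention avoids
seam bugs at ±180°. The default featurization is all interior φ and ψ
(2(n−1) columns for an n-residue chain); a residue selection lets users
match any specific feature count. Because angular features are periodic,
the pipeline sin/cos-embeds them by default before any linear method; both
raw-angle and embedded paths are supported. Multi-model PDB I/O is
delegated to biotite; all models must share one atom table.

## TICA

Covariances are estimated over lagged pairs only within each trajectory
(independent runs contribute no cross-boundary pairs), with the mean taken
over both pair endpoints and C_τ symmetrized as (C_τ + C_τᵀ)/2 so the
finite-data spectrum is real. C₀ is regularized by default with
ε·I, ε = 10⁻⁸·trace(C₀)/d, which keeps collinear sin/cos columns solvable;
the eigenvalue spectrum is invariant to feature rescaling because the
problem is generalized. The retained dimension defaults to the smallest d
capturing ≥ 95% of kinetic variance (cumulative Σλ²), overridable; the TICA
lag defaults to the MSM lag (10 frames). On high-dimensional angular data
with many noise directions the 95% rule is conservative (it can retain many
near-zero components); downstream clustering tolerates this, but passing an
explicit small `dim` is cheaper.

## Microstates and VAMP-2

k-means (k-means++ seeding, Lloyd iterations, best of 10 restarts by
inertia) is backed by scikit-learn; assignment is nearest-center with ties
to the lowest index. The VAMP-2 score of a discretization at lag τ is the
sum of squared singular values of C₀₀^{-1/2} C₀τ C_ττ^{-1/2} built from
one-hot state indicators; it is ≥ 1 (the constant function), exactly 1 for
a one-state discretization, and invariant to state relabeling.
Disconnected discretizations are scored on the largest strongly connected
set with a warning. k is selected by shuffle-split cross-validation over
whole trajectories (never frames — frames are autocorrelated), taking the
highest mean score with a one-standard-error tie-break toward smaller k.
The study preset fixes k = 10.

## MSM estimation and validation

Counting is sliding-window by default (maximal data use); strided counting
is available. Estimation is restricted to the largest strongly connected
component of the count graph (ties to the block containing the lowest state
index). The default estimator is the reversible maximum-likelihood fixed
point on symmetric auxiliary variables x_ij (converged when max|ΔT| <
10⁻¹⁰, capped at 10⁶ iterations, error with residual on failure); detailed
balance is what licenses the committor back-relation q⁻ = 1 − q⁺ used by
the flux module. The default lag is 10 frames = 1 ns at the 0.1 ns frame
spacing of the study preset. Implied timescales −τ/ln|λ| are reported as
NaN (never dropped) where eigenvalues are non-real or non-positive.

The Chapman–Kolmogorov test compares the set-to-set (or microstate)
transition matrix re-estimated at lag kτ against the k-th power of the
lag-τ matrix for k = 1..5. The pass criterion is max relative deviation
≤ 5% over entries whose propagated probability is ≥ 10⁻³; smaller entries
are flagged, not compared. Caveat: with few transition events (the study
preset's hidden chain produces ~25 jumps per 5000-frame trajectory) the
off-diagonal entries are sampling-noise-dominated and can deviate by tens
of percent even for data drawn exactly from a Markov chain, while the
diagonal self-transition probabilities — the quantities CK panels plot —
agree to better than 2%. The pipeline therefore records the CK result as a
diagnostic rather than aborting the run; on densely sampled two-state
chains (10⁵ steps) the 5% criterion is met outright.

## PCCA+

Memberships come from the span of the first m right eigenvectors (computed
via the symmetrized similarity transform D^{1/2} T D^{-1/2}, so they are
real) using the inner-simplex vertex search: the row farthest from the
origin seeds the simplex and successive Gram–Schmidt-deflated farthest rows
complete it; χ = X·X[vertices]⁻¹, tiny negatives (|·| < 10⁻¹⁰) clipped and
rows renormalized. Complex or non-positive eigenvalues among the first m
mean the spectrum does not support m metastable states and raise an error
advising smaller m. Crisp labels are row-argmax; macrostate weights are
χᵀπ. Endpoint auto-detection takes the modal macrostate of the first and
last 100 frames of each trajectory (majority vote across trajectories),
errs if they coincide, and always respects a user override. Macrostates
are named SA (source), SB (sink), and S1, S2, … by decreasing stationary
weight — the ordering of the intermediates is a labeling convention of this
package only.

## TPT

The forward committor solves the linear system of its defining recursion
directly; a genuinely singular system (intermediates that can reach neither
A nor B) raises with the trapped states listed. Intermediates that reach A
but not B legitimately get q⁺ = 0, so disconnected endpoint pairs yield
zero total flux rather than an error. The backward committor is 1 − q⁺ by
default (reversible convention); a general time-reversed solve is available
behind a flag. Gross flux f_ij = π_i q⁻_i T_ij q⁺_j (zero diagonal), net
flux max(f_ij − f_ji, 0); total flux is conserved between A's out-edges and
B's in-edges to 10⁻¹⁰ relative. Coarse-graining sums net flux across
macrostate boundaries and re-antisymmetrizes. Pathway decomposition is
iterative maximum-bottleneck (widest-path) extraction with a modified
Dijkstra, ties in width broken toward the lexicographically smallest path;
it stops at a residual below 10⁻³ of the total (configurable to 0 for a
complete decomposition). Percentages are 100·f_i/Σf_j; when reproducing
published tables the denominator may be supplied explicitly because printed
totals are rounded to 3 significant figures (one published table's leading
percentage only reproduces against its rounded total). Fluxes are reported
per lag step by default; per-second conversion via the frame spacing is
opt-in, since printed s⁻¹ labels cannot be verified from totals alone.

TPT can be run on microstates and then coarse-grained, or directly on the
macrostate-crisp trajectories; the pipeline uses the first route and the
CLI exposes both.

## Observables

RMSD uses the Kabsch SVD superposition with a proper rotation enforced
(det = +1); collinear or <3-atom selections are degenerate errors. RMSF is
measured about the mean structure after two passes of iterative alignment.
B = (8π²/3)·RMSF². DCCM normalizes displacement covariances to [−1, 1]
after superposition, with zero-fluctuation atoms flagged as NaN. SASA is
Shrake–Rupley with a 1.4 Å water probe and 960 golden-spiral sphere points
per atom (quadrature error < 1% on small systems; doubling the points is a
test), with a small built-in element radius table. Loop-distance presets
are configuration inputs: the exact ZA/BC-loop residue ranges of any
specific protein must be supplied by the user, and outputs are qualitative
comparators only.

## Synthetic data

The generators define the test conditions. `make_metastable_chain` builds
reversible block chains (symmetric random intra-block weights with a strong
self-weight, so the spectrum is positive, as befits lazy metastable
dynamics; p_inter mass leaks uniformly across blocks). `simulate_langevin`
integrates overdamped Euler–Maruyama dynamics, whose harmonic-well
stationary variance (kT) and double-well symmetry give closed-form checks.
`emulate_dihedral_dataset` reproduces the study's data shape — 10
trajectories × 5000 frames × 139 angular features at 0.1 ns spacing — by
driving wrapped-Gaussian feature noise (default σ = 25°) around per-state
mean angle vectors with a hidden 5-state chain (self-probability 0.995,
uniform leak, giving mean dwells of ~200 frames = 20 ns against a 1 ns lag).
Trajectories start in the planted source state and are resampled until the
final window's modal state is the planted sink, emulating a relaxation
experiment with known endpoints. All generators draw from a single seeded
generator per call and are bit-reproducible.

What passing on these data does **not** show: real backbone-dihedral
trajectories have anisotropic, state-dependent noise, fuzzy state
boundaries, and non-Markovian memory at short lags; the emulator's states
are exactly Markov and spherically noisy, so recovery rates here are upper
bounds on real-data performance. No force-field energetics or solvent
effects are represented, and nothing here reproduces actual BRD4
conformational ensembles.

## Problem sizes used in the test suite

The acceptance-level checks run the full study-shaped dataset
(10 × 5000 × 139) once for the end-to-end recovery test and the acceptance
script, with a VAMP grid of {2, 3, 5, 8, 10} × 3 cross-validation folds at
5 restarts; unit tests use reduced shapes (e.g. 5 × 1500 × 24 with 3 planted
states) that preserve every contract at a fraction of the cost. Chain
estimator checks use 10⁵ sampled steps; Langevin closed-form checks use
10⁶ (harmonic variance) and 3–4 × 10⁵ steps (double-well symmetry and
committor).
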