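# Methods

## Scope and design

The package implements the computational core of a reaction-pathway +
trajectory-dynamics study at desk scale. The expensive physics (QM/MM
energies of a solvated protein, microsecond MD) is replaced by two pluggable
stand-ins so that every algorithm is testable against independent oracles:

* **Analytic potential surfaces** behind one contract (`PotentialSurface`:
  `energy(x)`, `gradient(x)` on flat configuration vectors). Shipped surfaces:
  harmonic wells, the standard four-Gaussian Müller–Brown benchmark, and a
  two-coordinate *bond-swap* surface (below). Every shipped surface passes a
  central-difference gradient check at 1e-5 relative.
* **A synthetic trajectory generator** producing two-domain point systems
  with planted displacement modes, known time signals, and isotropic noise —
  exact ground truth for RMSF, PCA and DCCM.

## Weighted superposition and RMS

Best-fit RMS uses weighted Kabsch superposition: centroids from the weight
vector, rotation from the SVD of the weighted covariance, sign-corrected to a
proper rotation. Per-point weights select the reaction region — binary
weights (1 inside the region, 0 outside) are the intended use, mirroring the
convention of weighting only the quantum region in path RMS measurements; an
arbitrary non-negative weighting (e.g. masses) is accepted.

Degeneracies: with fewer than 3 positively weighted points the rotation is
undefined — a warning is issued and a translation-only fit returned. A
collinear weighted set leaves the rotation ambiguous about the line but the
*minimized RMS is still well-defined*; the Kabsch value is returned with a
warning. All-zero weights raise.

## Minimization

Two minimizers sit behind `minimize`: steepest descent with Armijo
backtracking (monotone by construction) and a quasi-Newton mode delegating to
L-BFGS with an RMS-gradient stopping callback. Both terminate when the RMS
gradient (per degree of freedom) falls below `grad_tol`; results never have
higher energy than the start. The quasi-Newton mode is treated as a generic
monotone second-order minimizer contract, not a re-implementation of any
specific program's algorithm.

## Replica-path optimization

The chain objective is the sum of per-replica energies plus two penalties:

* spacing: `K_rms · Σ (rms(i, i+1) − ⟨rms⟩)²` with ⟨rms⟩ recomputed every
  step (self-consistent mean — the simplest reading of the averaged form);
* angle: for each interior replica, cos θ from the law of cosines on the
  triangle (rms(i−1,i), rms(i,i+1), rms(i−1,i+1)), oriented so a straight
  chain has cos θ = +1; `K_angle · (COSMAX − cos θ)²` applied per vertex only
  when cos θ < COSMAX.

Defaults K_rms = 2000 energy/Å², K_angle = 100 (energy units), COSMAX = 0.95,
N_REP = 16. COSMAX is treated as a dimensionless cosine threshold (its
occasionally seen "radian" labeling is dimensionally inconsistent with a
cosine-based penalty and is not adopted).

The whole chain is one flattened variable vector under the quasi-Newton
minimizer; endpoints are frozen (they are separately minimized basin
structures, and freezing prevents basin drift during chain relaxation).
Surface gradients enter analytically; the penalty gradient is taken by
central differences (h = 1e-6) — the penalties are cheap functions of chain
geometry only, and this keeps the implementation independent of the RMS
flavor (plain or best-fit) in use.

**Convergence rule.** The run stops after 10,000 steps, or as soon as both
the total-pathway RMS gradient < 0.01 and the per-step objective change < 1.0
have held for 30 consecutive accepted steps. When the underlying minimizer
stalls (no further decrease representable) before the 30-step streak
completes, it is restarted with a fresh Hessian so the step count genuinely
accumulates; a run that terminates without meeting the rule reports
`converged = False` with the reason.

**Numerical regularization.** Inside the optimizer (only), segment distances
are smoothed as sqrt(d² + ε²) with ε = 1e-5 Å. At normal segment lengths the
relative effect is ~ε²/2d² (≈ 10⁻⁸ at d = 0.05 Å); at a collapsed segment it
removes the law-of-cosines singularity, so collapse shows up as a large,
smooth restoring force instead of a line-search failure. The public penalty
functions are exact (no smoothing). A fully degenerate chain (all replicas
identical) has zero penalties by convention; a partially collapsed chain is a
geometry error naming the replica.

**Spacing regularity.** The deviation-from-mean spacing penalty is a soft
restraint: where per-replica energy differences are comparable to
K_rms·⟨rms⟩², replicas drift toward low-energy regions and spacing becomes
uneven. On a gentle valley (energy scale well below the penalty scale) the
converged chain's segment-RMS coefficient of variation is below 5%; on the
steep Müller–Brown surface at the default K values it is not — which is
precisely why the protocol includes the endpoint-refinement stage. Refinement
(`refine_endpoints`) re-interpolates a fresh 16-replica chain between the
replicas `window` places either side of the highest-energy replica and
re-optimizes with the same parameters; on Müller–Brown it reduces the barrier
error from ≈0.54 to ≈0.19 energy units (grid-oracle reference). Ties in the
profile argmax break to the lowest index.

**2D toy embedding.** For two-dimensional surfaces the replicas are
single-point frames carrying the (x, y) configuration, and the chain uses
fit-off (plain) RMS distances — best-fit superposition is degenerate for
single points. Multi-point molecular frames default to best-fit RMS, for
which the penalties are rigid-motion invariant.

## Restrained coordinate driving

The restraint functional is `k (d₀ − d_eq)²` (no ½ factor — any constant
only rescales the effective k, and all behavior checks are
factor-independent). Driving performs `n_steps` (default 100)
restrained-minimization cycles; the `constant` schedule (default) restrains
to the final target from cycle 1 — the direct reading of "drive to the target
in 100 steps of restrained minimization" — while `linear` ramps the target
from the starting distance. Multiple restraints drive simultaneously on a
shared schedule; conflicting targets on the same pair are rejected. After
release, the relaxed structure is assigned to the nearest reference basin and
the assignment reported — release can legitimately fall back to the reactant,
and silence would hide that.

## The bond-swap surface

Internal coordinates R1 (breaking bond) and R2 (forming bond):

    E = Morse(R1; D1, a1, r1_eq) + Morse(R2; D2, a2, r2_eq)
      + coupling · exp(−a1 (R1 − r1_eq)) · exp(−a2 (R2 − r2_eq))
      + cage_k · (R1 + R2 − cage_span)²

The repulsive coupling forbids both bonds being made at once (carving two
basins and one saddle out of the Morse sum); the weak cage term stands in for
the active-site pocket holding the non-bonded partner at finite distance —
without it the unbound state has no finite-distance minimum. Defaults
(D1 = 80, D2 = 90, a1 = 1.5, a2 = 2.0, r_eq = 1.6 Å, coupling = 220,
cage_k = 10, cage_span = 5 Å) give a reactant basin at (1.62, 3.47), a
product basin at (3.59, 1.63) — the reaction is exothermic — and one saddle
at (2.10, 2.21): the breaking bond is stretched 0.50 Å at the saddle while
the forming bond is still 0.61 Å long of equilibrium, i.e. a loose,
dissociative transition structure by construction. The stationary-point
census (2 minima, 1 saddle) is verified numerically at construction and is
stable under ±10% parameter perturbation. A Cartesian embedding over three
labeled points (Os, Pg, Ow) exposes the same energy to the RESD driver and
the distance monitor; rigid motions are exact zero modes of that embedding.

Monitored-distance thresholds used to read bond order off an optimized chain:
breaking = r1_eq + 0.5 Å, bonding range = r2_eq + 0.1 Å. These are reporting
conventions, not model parameters; the dissociative ordering is robust to
reasonable variations because R1 leads R2 along the whole approach to the
saddle.

## Trajectory analyses

Alignment superposes every frame on a reference over a selection; the default
reference is the iterated mean structure (re-fit, re-average until the mean
moves < 1e-6 Å per point). Analyses assume an aligned trajectory; Δr is
displacement from the time-average position (the standard positional
fluctuation convention). RMSF is whole-trajectory. PCA eigendecomposes the
3n×3n covariance (normalized by n_frames); eigenvalue order is descending,
projections are taken on the retained modes, eigenvalue sum equals the
covariance trace to 1e-9 relative. DCCM entries are clipped to [−1, 1]
against roundoff; a zero-variance point gets NaN row/column with a warning.
Classification bins are (−1, −0.25] anticorrelated, (−0.25, 0.25) neutral,
[0.25, 1) correlated — boundary values outward, resolving the ambiguity of
half-open captions at ±0.25. The strongest anticorrelated pairs export as an
edge list for 3D rendering.

## Synthetic trajectories

coords(t) = base + Σ_k A_k · u_k · s_k(t) + noise, with unit-norm mode fields
u_k, sinusoidal signals of incommensurate frequencies (variance analytically
A_k²/2) or an Ornstein–Uhlenbeck option for MD-like autocorrelation, and
isotropic Gaussian noise. Mode shapes: anti-phase block translation (exact
±1 correlations — used for exact-recovery tests), hinge opening (linearized
rotation of the mobile block about the domain interface), twist (rotation
about the mobile block's own axis), and local wiggles (a random direction on
a small contiguous group). Mode fields other than the exact anti-phase one
are projected orthogonal to the 6 rigid-body fields of the base geometry, so
rigid-body alignment leaves them intact to linear order. Ground truth carries
the exact mode vectors, ideal per-point RMSF and the ideal correlation
matrix (cov_ij = Σ_k A_k² var(s_k) u_ik·u_jk + 3σ²δ_ij).

Scenario defaults (chosen once as plausible two-domain dynamics; 100 points,
1200 frames): *coherent_holo_like* = hinge amplitude 3.0 Å + twist 1.8 Å,
noise σ = 0.10 Å — a few large collective motions, as in a ligand-bound
system; *incoherent_apo_like* = 20 weak local modes (0.5 Å on the mobile
block, 0.25 Å on the core), noise σ = 0.35 Å — distributed incoherent
flexibility. Under these conditions the coherent scenario's PC1+PC2 fraction
is ≈0.81 vs ≈0.02 incoherent, the incoherent inter-domain strong-correlation
(|C| > 0.25) fraction is 0, and the mobile region's mean RMSF exceeds the
core's in both.

**What the generator does not emulate:** anharmonic basin hopping, solvent
damping, sequence-specific contacts, timescale separation beyond a single
autocorrelation time. Passing tests demonstrate that the *analysis machinery*
recovers planted signal correctly and that the qualitative bound/free
contrast is detected when present — not that any particular real system shows
that contrast.

## Problem sizes and determinism

Test and acceptance runs use 16-replica chains on 2D/9D toy surfaces,
trajectories of 10²–10⁴ frames and ≤100 points — sizes chosen so the full
suite runs in well under a minute per module on one CPU. All stochastic
stages take explicit seeds; identical inputs give bitwise-identical
trajectories, traces and optimization histories.

## Known limitations

* The penalty-based chain is not a nudged elastic band: no spring-force
  projection, no climbing image, so the highest replica slightly
  underestimates the saddle; refinement mitigates but does not eliminate
  this.
* The spacing penalty's softness (above) makes replica density
  energy-dependent at default K values on steep surfaces.
* Basin assignment after release is by configuration-space distance to the
  provided references; for Cartesian systems with large rigid drift a
  shape-based assignment would be more robust.
* The XYZ reader accepts only well-formed fixed-column-count records; no
  velocities, no lattice vectors. PDB reading is metadata-only (labels,
  residue numbers, chains) with no chemistry perception.
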