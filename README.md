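# repath

Replica-path (chain-of-states) minimum-energy-pathway optimization,
restrained coordinate driving, and trajectory dynamics analysis
(RMSD / RMSF / essential-dynamics PCA / DCCM), exercised on pluggable
analytic energy surfaces and synthetic two-domain trajectories.

## Who this is for

Modeling an enzymatic reaction such as ATP hydrolysis in a type-II
topoisomerase ATPase domain involves two computational workflows:

1. **Reaction pathways.** Given reactant and product structures, find the
   minimum energy pathway (MEP) over the potential surface and read off the
   activation energy and the order in which bonds break and form — e.g.
   whether the Pγ–O bond to the leaving group breaks *before* the nucleophile
   bonds (a dissociative mechanism). Product structures are manufactured by
   *restrained coordinate driving* (RESD): minimize under a quadratic distance
   restraint that forces the new bond, then release and re-minimize.
2. **Conformational dynamics.** Given an MD trajectory of the two-domain
   dimer, quantify how ligand binding changes the collective motions:
   per-residue flexibility (RMSF), dominant collective modes (PCA of the
   positional-fluctuation covariance), and correlated/anticorrelated residue
   motions (the dynamic cross-correlation matrix, DCCM).

This package implements both workflows as a reusable library with a CLI.
Production-scale QM/MM energies and microsecond MD are out of scope; instead,
the algorithms run on closed-form benchmark surfaces (Müller–Brown, a
two-coordinate "bond-swap" reaction surface) and on synthetic trajectories
with planted, analytically known motions — so every result can be checked
against an independent oracle.

## The methods

**Replica path.** A reaction path is a chain of N_REP = 16 replicas seeded by
linear interpolation between reactant and product. The chain minimizes

    O(path) = Σ_i E(x_i)
            + K_rms   Σ_i  (rms(i, i+1) − ⟨rms⟩)²
            + K_angle Σ_i  (COSMAX − cos θ_i)²   [only where cos θ_i < COSMAX]

where rms(i, i+1) is the best-fit weighted RMS distance between adjacent
replicas, ⟨rms⟩ its chain average (spacing stays regular), and cos θ_i is
obtained by the law of cosines from the triangle of RMS distances at replica
i (the chain cannot double back). Defaults: K_rms = 2000 energy/Å²,
K_angle = 100, COSMAX = 0.95. Optimization runs up to 10,000 steps or until
both the total-pathway RMS gradient < 0.01 and the objective change < 1.0
hold for 30 consecutive steps; endpoints stay frozen. A refinement stage
re-interpolates a fresh 16-replica chain bracketing the highest-energy
replica and re-optimizes, sharpening the barrier estimate.

**RESD.** A quadratic restraint k (d₀ − d_eq)² is added to the energy and the
structure is minimized for 100 restrained cycles (driving the forming bond to
1.6 Å in the reference protocol), then the restraint is removed and the
structure relaxed to RMS gradient ≤ 1e-4. The basin actually reached
(reactant vs product) is always reported, never assumed.

**Trajectory analyses.** After rigid-body alignment (iterated-mean
reference), Δr_i is each point's displacement from its time average:
RMSF_i = sqrt⟨|Δr_i|²⟩; PCA diagonalizes the 3n×3n covariance of the
flattened fluctuations; the DCCM is C_ij = ⟨Δr_i·Δr_j⟩ /
sqrt(⟨Δr_i²⟩⟨Δr_j²⟩), binned blue/white/red at C = ±0.25 with boundary
values assigned outward.

## Worked example

The toy reaction study end to end — RESD product build, 16-replica chain,
optimization, refinement, monitored distances:

```bash
repath run reaction --seed 1 --out runs/reaction
```

prints (abridged):

```json
{
  "release_basin": "product",
  "release_rms_gradient": 1.452603885099441e-07,
  "driven_distances": [1.6095525435017648],
  "converged": true,
  "steps_taken": 352,
  "activation_energy": 11.91053767034792,
  "ts_index": 3,
  "refined_activation_energy": 11.310468801895496
}
```

Reading this: the forming bond was driven to 1.61 Å (target 1.6 Å); after
releasing the restraint the structure relaxed into the **product** basin with
an RMS gradient of 1.5e-07 ≤ 1e-4; the chain converged by the 30-step rule
after 352 steps; the barrier read from the optimized profile is 11.9 energy
units (11.3 after the refinement stage — the independently computed
grid-oracle saddle gives 11.42). The `monitor.csv` artifact shows the
breaking bond R1 passing its rupture threshold at replica 4 while the forming
bond R2 only reaches bonding range at replica 7 — the dissociative ordering.

The dynamics contrast:

```bash
repath run dynamics --seed 7 --out runs/dynamics
```

reports for the coherent (ligand-bound-like) scenario a PC1+PC2 variance
fraction of 0.808 and an inter-domain mean |C| of 0.342, against 0.023 and
0.015 for the incoherent (free-like) scenario — the bound system moves in a
few large collective modes with strong inter-domain coupling, while the free
system shows no large concentrated correlation groups. In both, the mobile
(transducer-like) region fluctuates more than the core.

Library use mirrors the CLI (`repath.interpolate_endpoints`,
`repath.optimize_path`, `repath.drive`, `repath.dccm`, ...); see the module
docstrings and `docs/methods.md`.

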