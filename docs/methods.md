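# Methods

This note records the models, estimators, numerical choices and known
limitations behind `msmkin`, at the level of detail a user needs to judge
what the numbers mean.

## Order parameters and state classification

The conformational coordinates are those standardly used for class B GPCR
ECD dynamics:

- **ECD tilt angle θ** — the angle, in [0°, 180°], between the sum of the
  backbone carbonyl C→O vectors over a user-declared helix residue range
  (for PAC1 the N-terminal ECD helix, residues 30–47) and the membrane
  normal. The raw summed vector is used even for kinked helices; no
  projection or folding is applied, because θ > 80° and θ ≈ 40° label
  different physical states and must not alias. The membrane normal is
  taken as +z of the frame; `compute_order_parameters(..., align=True)`
  (the default) first Kabsch-superposes every frame's 7TM core onto a
  reference so arbitrarily oriented trajectories are restored to the
  membrane frame before θ is read.
- **Group COM distances** — Euclidean distances between mass-weighted
  centers of mass of residue groups over backbone atoms N, CA, C, O
  (hydrogen-free standard atomic masses). Residue numbering is always
  verbatim from the source file; groups are declared by the user, never
  hard-coded.
- **State classifier** — a total function over (θ, d, d_ECL1, d_ECL3) with
  the precedence: d > 55 Å → *ECD-unrestricted*; else
  d_ECD-ECL3 − d_ECD-ECL1 ≥ 10 Å → *on-side*; else θ bands. The bands put
  edges midway between the canonical state centers: *open* [30°, 50°),
  *semi-open* [50°, 70°), *intermediate* [70°, 80°], *closed* > 80°;
  anything unmatched (including θ < 30°) is *intermediate*. All thresholds
  are configurable; definitions are validated pairwise disjoint.
- **Contacts** — residue pairs across two disjoint groups whose closest
  heavy-atom distance is below a cutoff. The 4.5 Å default is a package
  choice (no canonical value exists for this count); state it when
  reporting numbers.

Superposition uses the Kabsch SVD solution with the determinant correction,
so reflections are never returned; selections with fewer than 3 atoms or
(near-)collinear geometry are rejected because the optimal rotation is not
unique there. The batched RMSD kernel used by clustering evaluates the
Gram-trace identity with single-precision inputs (metric error ~1e−3 Å,
orders of magnitude below any meaningful cluster radius).

## Markov state models

- **Discretization**: Gonzalez farthest-point k-centers under fitted Cα
  RMSD. The first center is the first frame (or a seeded random frame);
  ties in the farthest-point selection break toward the lowest frame index,
  making runs bit-reproducible. The greedy radius is within 2× of the
  optimal k-center radius (tested against exhaustive optima on small
  instances). The default k grid spans 33–55 centers; a single k = 40 is
  used where one value is needed.
- **Counting**: sliding-window counts at lag τ (every frame pair τ apart),
  never across replica boundaries; strided counting is available.
- **Ergodic trimming**: estimation is restricted to the largest strongly
  connected component of the count graph; trimmed states are logged, not
  silently dropped.
- **Reversible MLE**: self-consistent fixed-point iteration on symmetric
  flow variables x_ij = x_ji,
  `x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j)`, converged when the largest
  relative change drops below 1e−10 (at most 1e6 iterations); T = x/x_i and
  π = x_i/Σx. Detailed balance of every returned matrix holds to better
  than 1e−8. Spectra are computed on the symmetrized matrix
  D^{1/2} T D^{−1/2} with `eigh`, so eigenvalues are real by construction
  and the routine raises if the input is not actually reversible.
- **Lag selection**: implied timescales t_i = −τ/ln λ_i over a lag grid;
  the model is used at the shortest lag where the curves are flat (for the
  receptor systems this plateau sits at 1.2–2.4 ns). m = min(10, k−1)
  timescales are reported; eigenvalues ≤ 0 yield NaN and a chain that never
  leaves a state is flagged as having no finite timescale.
- **Chapman–Kolmogorov test**: for each microstate set S, the
  stationary-weighted persistence probability propagated with T(τ)^n is
  compared against the model re-estimated directly at nτ. Error bands are
  2.58× the bootstrap standard deviation of the direct estimate, from
  resampling replicas with replacement (a single replica is first split
  into 8 contiguous segments). At n = 1 predicted and estimated coincide
  exactly, which doubles as a self-test.
- **PCCA**: classic sign-structure Perron Cluster Cluster Analysis —
  recursive bisection on the dominant right eigenvectors, splitting the
  cluster with the largest eigenvector spread at the sign change (at the
  midpoint when one-signed, which makes n = k the identity partition).
  This is deliberately the classic variant, not PCCA+; it is robust for
  well-separated metastable blocks and replaceable behind the same
  interface.

## Transition-path theory

Forward committors solve the standard linear system with q⁺ = 0 on A and 1
on B; backward committors come from the time-reversed chain (equal to
1 − q⁺ only under detailed balance, which is checked rather than assumed).
Gross flux f_ij = π_i q⁻_i T_ij q⁺_j; net flux is its positive
antisymmetric part; the total reactive flux is the net flow out of A. Flux
conservation at intermediate nodes is verified to 1e−10.

Pathways are extracted by iterative bottleneck decomposition: the widest
(max-bottleneck) A→B path under a deterministic lowest-index tie-break, its
bottleneck flux subtracted, repeated until the flux is exhausted. For
reversible chains net flux is acyclic along the committor, so the
decomposition is exhaustive (bottlenecks sum to the total flux).

The transition time between two state sets is **τ divided by the minimum
net flux in the transition path**. The phrase admits two readings and both
are computed: `mode="dominant"` (default) uses the bottleneck flux of the
first-extracted pathway; `mode="total"` divides by the total reactive flux.
Fluxes are per-lag probabilities, so times carry the lag's physical units
(ns here); doubling the lag with T → T² moves the estimate only at O(τ).

## Thermodynamics

- Free-energy surfaces: 2D histograms over an order-parameter pair
  (default 36 θ-bins × 30 d-bins over [0°, 180°] × [20 Å, 80 Å]),
  Boltzmann-inverted as F = −RT ln(ρ/ρ_max) so the densest bin sits at
  exactly 0; empty bins are masked and impassable. R = 1.98720×10⁻³
  kcal/(mol·K); the default temperature is 310 K (RT = 0.6160 kcal/mol).
- Barriers: the minimax path value over the 4-connected occupied-bin graph
  minus the free-energy minimum of the starting basin — an operational
  saddle height. The forward/backward difference equals the basin-minimum
  offset by construction. Whether a published 2D-map barrier was read this
  way or visually is generally unknowable; minimax is the reproducible
  definition used throughout.
- Affinity conversion: ΔG_b = RT ln K_d with K_d in molar units (1 M
  standard state); the inverse is exact to 1e−12 relative over
  K_d ∈ [1e−12, 1] M. At 310 K, K_d = 0.5 nM ↦ −13.2 kcal/mol and
  500 nM ↦ −8.9 kcal/mol (ratio 1.476).
- MM-GBSA aggregation: this package never evaluates generalized-Born
  energies. It consumes per-replica totals and per-frame per-residue tables
  exported by an external engine, reports the mean and *sample* (n−1)
  standard deviation over replicas (the five-replica error-bar convention),
  time-averages per-residue contributions over a frame window (e.g. the
  trajectory tail), ranks contributors, and checks the decomposition's
  additivity against a supplied total column when present.

## The synthetic generator and what passing it proves

The generator stands in for the ~20 µs of receptor MD that a desk-scale
test cannot regenerate. Its defaults are the study conditions the pipeline
targets:

- 4 metastable macrostates (closed, semi-open, open, ECD-unrestricted) with
  per-state (θ, d) means (90°, 47 Å), (60°, 50 Å), (40°, 53 Å),
  (60°, 65 Å) — each inside a distinct classifier region, with the
  restricted states' d below 55 Å and the unrestricted state above.
- A reversible true transition matrix built from a symmetric rate skeleton
  (main pathway closed↔semi-open↔open with weaker shortcuts), per-state
  self-transition probability exactly 0.97 at the generation step, λ₂ =
  0.972 and a non-uniform stationary distribution ≈ (0.205, 0.318, 0.273,
  0.205). Reversibility is by construction, so downstream detailed-balance
  checks are meaningful.
- 5 replicas × 5,000 frames at Δt = 0.2 ns by default — per-replica frame
  counts inside the 4,519–14,281 conformations-per-trajectory range of the
  target ensembles. Recovery statistics are quoted at 5 × 20,000 frames,
  where the stationary distribution of a chain this slow is statistically
  resolvable to L1 ≈ 0.03.
- Toy conformers of 40 pseudo-residues with full backbone (N, CA, C, O):
  a rigid ring-like "7TM" core (with mirror-symmetric ECL1/ECL3 probe
  groups, so the default states are never on-side) and an ideal "ECD"
  helix whose carbonyl vectors are exactly axial. Each state rotates the
  helix by θ about y and places its backbone COM at exactly distance d from
  the core COM along the direction tilted −θ/2 from +z. Putting the COM
  opposite the tilt prevents any single global rotation from absorbing both
  the orientation and position differences between states, which keeps
  inter-reference Cα RMSD in the 3.5–10 Å range — far above the 0.2 Å
  Cartesian emission noise (separability is enforced as reference RMSD
  > 4σ).
- Every frame receives an independent uniformly random rigid-body rotation
  and translation, so no stage can shortcut past superposition.
- Seeding: one master seed; per-replica streams derive from fixed
  (seed, replica) offsets; everything is bit-reproducible and recorded in
  the bundle's run metadata.

What the generator does **not** emulate — and hence what green tests do not
prove about real MD: frames are conditionally independent given the hidden
state (no intramolecular relaxation, so the discretized process is exactly
Markov at lag 1 rather than approximately Markov at a selected lag); there
is no density along transition paths, so fine-binned free-energy basins are
disconnected islands (barrier analyses on synthetic data need coarse bins);
noise is isotropic Gaussian rather than structured; and the conformers are
toys, not receptor coordinates. The generator validates estimator
correctness and pipeline plumbing, not force-field realism.

Recovery is scored by: best-matching (Hungarian) purity between PCCA
macrostates and hidden labels; L1 errors of the lumped macrostate
transition matrix and stationary distribution against the truth propagated
to the analysis lag; relative error of the slowest implied timescale; and
relative errors of all pairwise TPT transition times. At the quoted scale
the medians over 20 seeds are ≈1.0 purity, ≈0.025 L1, ≈1.5% timescale
error and ≈2.5% transition-time error — comfortably inside the 0.95 / 0.03
/ 15% / 25% targets the suite asserts.

## Degenerate inputs and tie-breaking

Superposition rejects < 3 or collinear atoms; RMSD of 1–2 atom selections
falls back to closed forms. k-centers ties break to the lowest frame
index; widest-path ties to the lowest state index; PCCA relabels clusters
by first microstate index. Disconnected count matrices raise from the
low-level estimator and are trimmed (with a logged report) by the
high-level one. Committor systems that are singular because intermediates
cannot reach A or B raise with that diagnosis. Zero reactive flux is an
error for transition times, never an infinity silently propagated —
except in the all-pairs convenience scan, where unreachable pairs are
reported as inf by design.

## Problem sizes used in the checked results

Unit and property tests run on instances small enough to check against
brute-force oracles (≤ 10 points for exhaustive k-centers, 6×6 grids for
all-paths barrier minimax, 10⁶ random walks for committors). The recovery
suite and the acceptance script use 20 seeded bundles of 5 × 20,000 frames
(2×10⁶ frames of 160 atoms in total), a scale at which every threshold
above is met with margin while the whole computation stays in the
few-minute range on one CPU.
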