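# Methods

`pacsfe` reimplements a computational pipeline for pressure-dependent
protein–protein dissociation: cascade-selection adaptive sampling of
dissociation pathways, Markov-state-model (MSM) estimation of the free-energy
profile along the inter-center-of-mass distance *d*, the standard binding free
energy with a bound-volume correction, and the accompanying structural
analyses (hydration shells, interface waters, hydrogen-bond networks, salt
bridges, compressibility, conformer populations, transition-state-theory
kinetics).  The all-atom engine is replaced by an overdamped Langevin toy
system with an analytically known ground truth, so the entire pipeline is
testable at desk scale.

## The toy system

A walker (the ligand center of mass) diffuses in a pressure-parameterized
binding potential around the origin (the receptor center of mass), in reduced
units (kT = 1, lengths in Å, times labeled ps so cycle accounting maps 1:1
onto the all-atom protocol).

**Radial funnel.**  The default potential is a flat-bottomed attractive well
joined to zero by a C¹ smoothstep wall:

    U(r) = -ε                       r < r0
    U(r) = -ε (1 - 3t² + 2t³)       t = (r - r0)/w in [0, 1]
    U(r) = 0                        r > r0 + w

with wall width w = sqrt(6 ε / κ) (so that max |U''| = κ, the `stiffness`
parameter) and r0 chosen so the half-depth point sits at `bound_radius`.
A reflective wall at `wall_radius` (default 30 Å) emulates the finite
simulation box and normalizes the unbound state.  The flat bottom is a
deliberate choice: the standard-state correction used downstream models the
bound state as a square well of depth ΔW over a volume V_b, and a
flat-bottomed toy is the regime in which that model is essentially exact, so
estimator errors are attributable to the estimator rather than to the
correction's own approximation.

**Pressure.**  Pressure enters as a linear shallowing of the well,
ε(p) = `well_depth_0` − `pressure_coefficient` · (p − 0.1 MPa), emulating the
experimental finding that binding weakens as pressure rises through enhanced
hydration.  Defaults: ε(0.1 MPa) = 7 kT, coefficient 0.025 kT/MPa, giving
7.0 / 5.75 / 4.5 kT at 0.1 / 50 / 100 MPa.  These are not a claim about any
specific complex's energetics; they are chosen so that (a) the three
pressures are separated by 1.25 kT — resolvable above the estimator noise of
a desk-scale run — and (b) barrier recrossings occur spontaneously often
enough that every trial accumulates usable transition statistics.

**Dynamics.**  Euler–Maruyama overdamped Langevin steps,
x ← x + (D/kT) F Δt + sqrt(2 D Δt) η, with D = 0.3 Å²/ps and Δt = 10⁻³ ps.
At this Δt the discretization bias on the stationary distribution
(≈ βDκΔt/2 per local curvature unit) is below 0.01 kT everywhere.  D is
chosen so that the unbound transit from the well to the 25 Å threshold spans
several sampling cycles — as in the source system — rather than completing
inside a single cycle, which would leave the unbound region sampled once and
one-directionally.  Identical seeds give bit-identical trajectories; replica
noise streams are keyed by (base seed, trial, cycle, replica, round) so
results are independent of execution order.

**Validation.**  Equipartition in a harmonic well (var = kT/k within 5% at
10⁶ steps) and a 10⁸-step equilibrium run whose log-histogram matches the
quadrature per-bin free energy within 0.2 kT.

## Adaptive sampling (cascade selection)

Per cycle, `n_replicas` (10) segments of `md_length_per_cycle` (100 ps) run
from the current seeds; snapshots every `rank_stride` (1 ps) are rank-ordered
by the selection coordinate and the top `n_select` (10) become the next
cycle's seeds; the loop stops at `cv_threshold` (25 Å) or `max_cycles` (200).
Seeds restart position only — overdamped dynamics has no velocities, so
"fresh velocities" becomes "fresh noise stream".  Ties in ranking break
toward earlier time, then lower replica index.  If a cycle yields fewer
distinct snapshots than seats, the ranked list repeats cyclically.

After termination, each cycle's stored seed set is rerun with fresh noise
(`extra_rounds`) and appended to the archive.  Trials that dissociate in few
cycles additionally receive extra sets until the trial's pool reaches
`min_pool_segments` (1000) segments (capped at `max_extra_rounds` = 24) —
the analogue of repeating additional simulation sets per trial until the
implied-timescale test is satisfied, with the set count varying by trial.
Cost accounting reports lineage time (cycle length × cycles) and aggregate
cost (× replicas); extra rounds are accounted separately.

A `selection="random"` mode reseeds from uniformly chosen snapshots with an
identical budget; it is the no-selection control used to demonstrate
acceleration (a 12 kT well dissociates under selection in ~5–10 cycles and
never within 40 cycles under random reseeding).

## MSM free-energy estimation

Per trial, the pooled coordinate samples are clustered into k = 30 k-means
microstates and the fine-stride series is assigned to nearest centers.
Because cascade-selection archives are strongly mass-imbalanced (walkers
stall in the bound basin), the clustering pool is density-balanced first:
each 1 Å band of *d* contributes at most `cluster_band_cap` (3000) samples.
Only clustering sees the balanced pool; transition counting always uses the
full archive.

Transition counts use a sliding window at lag τ (default 1 ps for the toy;
the published all-atom analysis used 30 ps — the toy's diffusive relaxation
is orders of magnitude faster) and never cross segment boundaries.  The
model is restricted to the largest connected component.  Three estimators:

* `reversible` (default): maximum-likelihood reversible transition matrix by
  the standard self-consistent fixed-point iteration.  Its stationary
  distribution is consistent even under adaptively-biased visitation — the
  essential property for cascade-selection data, where the naive estimator's
  stationary vector is just the (biased) empirical visitation frequency.
* `symmetrized`: row-normalized (C + Cᵀ)/2; detailed balance by
  construction; appropriate for equilibrium trajectory pools.
* `nonreversible`: row-normalized raw counts.

Implied timescales t_i(τ) = −τ/ln λ_i(τ) are computed over a ladder of lags;
"converged" means the slowest timescale varies < 10% between the last two
lags.

**Profiles.**  Per-trial profiles are linearly interpolated onto a common
1 Å grid, shifted to min 0, and averaged (mean ± SD across trials).  Two
variants are kept: `pmf` = −kT ln π (the raw stationary-probability profile)
and `pmf_density` = −kT ln(π/V_cell), where V_cell is each microstate's
radial shell volume.  For an isotropic 3-D coordinate the raw profile
contains the 4πd² shell-volume growth and never flattens; the
density-normalized profile is the curve that levels off in the unbound
region and is therefore the one used for flat-tail detection and ΔW.

**Binding free energy.**  With a bound/unbound boundary *b*:

* ΔG_bind = −kT ln(P_b/P_u), P's by summing π on each side (averaged over
  trials);
* ΔG°_bind = −ΔW − kT ln(V_b/V°), where ΔW is the arithmetic mean of the
  flat-region density profile above its minimum (a probability-weighted
  variant is available), V_b the convex-hull volume (Qhull via scipy) of the
  bound-state walker positions sampled every 2 ps — per-trial hulls averaged
  before the correction — and V° = 1661 Å³ the 1 M standard-state volume.

The boundary is configurable; `auto` takes the smallest *d* beyond which the
density profile's slope stays below a tolerance for 5 consecutive Å.  The
operation's default tolerance is 0.05 kT/Å; the toy pipeline runs with
0.25 kT/Å because the per-point statistical noise floor of a desk-scale tail
is 0.1–0.3 kT, below which the stricter criterion never fires.

**Analytic reference.**  `analytic_reference` integrates the Boltzmann weight
(with the 4πr² Jacobian) over the same potential and returns the per-bin
profile, P_bound, ΔG_bind, and two standard forms: the method-consistent
reference −ΔW_true − kT ln(V_bound/V°) with V_bound the analytic bound-region
volume (this is what the sampled pipeline estimates), and the direct integral
−kT ln(Z_b/V°); the two coincide in the square-well limit.  At the default
conditions (seed 1) the full pipeline recovers −6.4 / −5.5 / −4.3 kT against
references −6.7 / −5.4 / −4.1 kT and orders the three pressures correctly in
all five noise-paired trials.

## Synthetic solvated structures

`generate_solvated_structure` builds two labeled bead clusters plus
oxygen-only point waters in an orthorhombic box.  Shells are defined by
distance to the nearest bead center ([0,3] and (3,6] Å, matching the
counting operators); region volumes come from hit-or-miss Monte Carlo under
a fixed sub-seed.  Shell counts are Poisson with mean
multiplier × (N/V_box) × V_shell, realized by inverse-CDF so that raising a
multiplier with the seed fixed can only raise the corresponding count; the
remaining waters fill the bulk uniformly by rejection sampling.  The
generator emulates one feature of real pressurized systems — elevated
near-solute water density relative to bulk — and nothing else: no hydrogen
atoms (hydrogen-bond analyses fall back to the distance-only criterion), no
water structure or orientations, no electrostriction, no protein flexibility.
Passing tests therefore demonstrate correct counting and density estimation,
not realism of hydration structure.

## Structural analyses

* **Hydration shells**: a water (counted at its oxygen) is first-shell iff
  its minimum distance to any solute atom is ≤ 3 Å (closed boundary),
  second-shell in (3, 6]; minimum-image convention for orthorhombic boxes.
  Densities are counts over Monte-Carlo shell volumes; r-ratios are shell
  density over bulk density.  Raw counts are always reported alongside.
  Neighbor search uses a KD-tree and is tested to equal the all-pairs brute
  force exactly.
* **Interface residues**: any-heavy-atom contact ≤ 4.5 Å with the partner
  chain in ≥ 80% of the window frames (window defaults to the trajectory's
  last half).  Interface waters re-run the shell counter on those residues'
  atoms only.
* **Hydrogen bonds**: donor–acceptor ≤ 3.5 Å and D–H···A ≥ 150°, with a
  distance-only mode for hydrogen-free models; H_PP counts protein–protein
  (intra + inter), H_PW protein–water, H_PWP waters bonded to two distinct
  protein chains (once per water).  Same-residue pairs and water–water bonds
  are excluded.
* **Salt bridges**: charged-group side-chain N/O atoms (LYS NZ; ARG NE/NH*;
  HIS ND1/NE2; ASP OD*; GLU OE*) within 4.0 Å; occupancy is the fraction of
  frames.
* **Compressibility**: κ_T = (⟨V²⟩−⟨V⟩²)/(k_B T ⟨V⟩) over the last half of
  the volume series (population variance); reduced (kT = 1) or 1/MPa units.
* **SASA**: Shrake–Rupley with a deterministic Fibonacci sphere (960 points
  per atom), probe 1.4 Å, bundled van der Waals radii; cross-checked against
  an independent implementation.  Points on exactly shared surfaces belong
  to the lower atom index, so coincident atoms count their surface once.
* **Conformers**: χ1 (N–CA–CB–CG, IUPAC sign) classifies frames inactive in
  [−45°, 135°) and active otherwise; ΔG_M = −kT ln(P_inactive/P_active); the
  boundary is left-closed/right-open by explicit convention.  RMSD uses
  Kabsch superposition with proper rotations enforced; representatives are
  medoid frames of k-means clusters on superposed α-carbon coordinates (a
  coordinate mean is not a physical frame).  Transition counting is a
  dwell-filtered crossing counter (default 10 frames) — deliberately simpler
  than full dihedral-transition analysis.

## Kinetics

Closed forms with CODATA 2018 constants at a default 300 K (the simulation
temperature): Eyring k_off = (k_BT/h) exp(−ΔG‡/k_BT) with ΔG‡ set to
|ΔG°_bind| (the convention adopted throughout: no barrier beyond the binding
free energy, so the rate is an upper-bound-style estimate — 30 k_BT gives
0.585 ≈ 0.6 s⁻¹); K_d = C₀ exp(ΔG°_bind/k_BT) with C₀ = 1 M, so the printed
positive-exponent form yields K_d < 1 M only for negative (favorable)
ΔG°_bind; V° = 10²⁷/N_A = 1660.54 Å³ (displayed 1661); elastic strain =
pressure/Young's modulus.  Energies crossing these functions carry explicit
unit tags (kT vs kcal/mol); mixing without conversion is a hard error.

## Problem sizes and numerical choices

The shipped defaults run the full three-pressure pipeline (5 trials × 10
replicas × ≤ 200 cycles plus pool-balancing extra rounds, 30-state MSMs,
lag-ladder validation) in a few minutes on one core; the equilibrium
validation runs use 10⁸ Langevin steps in chunks so noise buffers stay
small.  k-means uses scikit-learn (k-means++ under a fixed seed, n_init 10);
eigenproblems use dense LAPACK (k = 30); the reversible fixed point iterates
to 10⁻¹² relative change.  Degenerate inputs fail loudly: empty selections,
non-positive effective well depths (with the offending pressure named),
grids coarser than the well, coplanar hulls, reducible chains after
restriction.

## Known limitations

* The toy coordinate is one-dimensional (radial); orientational degrees of
  freedom, multiple pathways, and phase-resolved dissociation intermediates
  are not represented, and the phase-boundary annotation is optional
  metadata only.
* The linear pressure→depth model is a stand-in with a controllable ground
  truth, not a physical model of any specific complex.
* ΔW measured from the flat tail plus a hull V_b inherits the square-well
  model of the bound state; for potentials with soft walls and boundary
  detection overshoot the two effects partially cancel but do not vanish
  (≈ 0.1–0.4 kT at the shipped conditions).
* Hydrogen-free toy structures exercise only the distance-only hydrogen-bond
  criterion; the angular criterion is tested on constructed geometries.
* PDB support is fixed-column ATOM/HETATM with orthorhombic CRYST1 boxes;
  binary trajectory formats are out of scope.
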