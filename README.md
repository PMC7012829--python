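# pacsfe

Cascade-selection adaptive sampling, Markov-state-model binding free
energies, and hydration analysis for pressure-dependent protein–protein
dissociation — exercised end-to-end on a desk-scale Langevin toy system with
an analytic ground truth.

## What this is for

Hydrostatic pressures below ~100 MPa do not unfold proteins, but they do
weaken protein–protein binding by densifying the hydration shells and
pushing water into complex interfaces — the mechanism by which, e.g., a
chemotaxis response regulator's grip on the flagellar motor loosens in
high-pressure environments.  Measuring that effect computationally needs
three ingredients this package provides:

1. **Adaptive sampling** (`pacsfe.pacs`): parallel cascade selection —
   cycles of short parallel simulations whose snapshots are rank-ordered by
   the inter-center-of-mass distance *d*; the top-ranked snapshots reseed
   the next cycle, so dissociation events far beyond the reach of one
   contiguous trajectory are generated without biasing forces.
2. **MSM free energies** (`pacsfe.msm`): 30-state k-means discretization of
   *d*, lagged transition counting with implied-timescale validation, a
   reversible maximum-likelihood transition matrix (consistent under the
   adaptively biased sampling), the profile −kT ln π, and

       ΔG_bind  = −kT ln(P_b / P_u)
       ΔG°_bind = −ΔW − kT ln(V_b / V°),   V° = 1661 Å³

   where ΔW is the flat-tail offset of the profile above the bound minimum
   and V_b is the convex-hull volume of the bound-state ligand-COM cloud.
3. **Structural operators** (`pacsfe.hydration`, `pacsfe.conformers`,
   `pacsfe.kinetics`): first/second hydration-shell counts (N_1SW, N_2SW)
   and their densities relative to bulk, interface residues and interface
   waters, hydrogen-bond tallies (H_PP, H_PW, H_PWP), salt-bridge occupancy,
   volume-fluctuation compressibility, Shrake–Rupley SASA, χ1-based
   active/inactive conformer populations and ΔG_M, Kabsch RMSD,
   representative structures, and Eyring/K_d closed forms.

Instead of an all-atom engine, `pacsfe.model_system` ships an overdamped
Langevin walker in a pressure-parameterized binding funnel (pressure
linearly shallows the well) plus a synthetic solvated-structure generator
with controllable shell density multipliers.  A quadrature oracle
(`analytic_reference`) supplies the exact profile and ΔG°_bind for the same
potential, so every stage of the pipeline is verifiable.

## Worked example

```python
import numpy as np
from pacsfe import run_toy_pipeline

results = run_toy_pipeline(pressures=(0.1, 50.0, 100.0), seed=1)
for r in results:
    b = r.binding
    print(f"{r.pressure:6.1f} MPa  dG_std = {b.delta_G_bind_standard:6.2f} kT  "
          f"(reference {r.reference_delta_G_standard:6.2f} kT)  "
          f"dW = {b.delta_W:5.2f} kT  V_b = {b.V_b:6.0f} A^3")
```

prints (a few minutes on one core):

```
   0.1 MPa  dG_std =  -6.37 kT  (reference  -6.67 kT)  dW =  6.56 kT  V_b =   1381 A^3
  50.0 MPa  dG_std =  -5.45 kT  (reference  -5.40 kT)  dW =  5.54 kT  V_b =   1521 A^3
 100.0 MPa  dG_std =  -4.26 kT  (reference  -4.12 kT)  dW =  4.64 kT  V_b =   1134 A^3
```

Reading this: each line is the standard binding free energy of the toy
complex estimated by the full sampled pipeline (five adaptive-sampling
trials, per-trial MSMs, Eq. ΔG° above) next to the exact quadrature value
for the same potential.  Binding weakens monotonically with pressure
(−6.4 → −4.3 kT from 0.1 to 100 MPa), the estimates track the ground truth
to 0.05–0.30 kT, and the per-trial paired comparison orders the three
pressures correctly in 5 of 5 trials.  ΔW is the height of the flat unbound
tail above the bound minimum; V_b the bound-state hull volume entering the
standard-state correction.

The same pipeline is available from a shell:

```bash
pacsfe demo --seed 1 --out out/            # quick small-scale smoke run
pacsfe pacsmd --trial 0 --seed 1 --out arc/  # one adaptive-sampling trial
pacsfe msm --archive arc/ --lag 1.0 --k 30 --out msm/
pacsfe kinetics --dg-kt 30 --temp 300
```

The last command prints the closed-form conversions: a 30 kT binding free
energy corresponds to k_off = 0.585 s⁻¹ ≈ 0.6 s⁻¹ by transition-state
theory at 300 K, K_d ≈ 9.4 × 10⁻¹⁴ M, the standard-state volume is
1660.54 ≈ 1661 Å³, and 100 MPa against a 3 GPa Young's modulus is a 3.3 %
elastic strain.

## Layout

| module | contents |
| --- | --- |
| `pacsfe.model_system` | toy potential, Langevin propagator, quadrature oracle, solvated-structure generator |
| `pacsfe.pacs` | cycle config, ranking/selection, adaptive loop, archive, cost accounting, COM distances |
| `pacsfe.msm` | microstates, transition estimators, implied timescales, profiles, binding free energy |
| `pacsfe.pipeline` | archive → MSM → ΔG° orchestration across pressures |
| `pacsfe.hydration` | shells, interface residues/waters, H-bonds, salt bridges, κ_T, bulk density, SASA |
| `pacsfe.conformers` | χ1 series, active/inactive classification, ΔG_M, RMSD, representatives, transition counts |
| `pacsfe.kinetics` | Eyring k_off, K_d, standard-state volume, elastic strain |
| `pacsfe.structure`, `pacsfe.io`, `pacsfe.cli` | containers, PDB/CSV/JSON + manifests, umbrella CLI |

See `docs/methods.md` for the model, estimator choices, parameter defaults
and their rationale, and known limitations.
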