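# nanokin

Quantitative analysis of enzymatic polyester degradation, built for
biocatalysis groups characterizing polyester hydrolases (cutinase-like
serine hydrolases acting on PCL and PET), plus the trajectory stability
metrics used to rationalize their thermal behavior.

## The science

**Turbidimetric nanoparticle kinetics.** Hydrolysis of an insoluble
polyester dispersed as a nanoparticle suspension is followed by the decay of
turbidity τ at 600 nm. Under a geometric-scattering approximation
(τ ∝ N·r² at constant particle number) with constant surface erosion,
y(t) = √(τ(t)/τ₀) falls linearly during the initial phase. The initial rate
R = −dy/dt saturates hyperbolically in the enzyme concentration [E] because
catalysis requires adsorption to the particle surface:

    R([E]) = k_τ · K_A·[E] / (1 + K_A·[E])

with k_τ (min⁻¹) the hydrolysis rate constant based on the turbidity change
and K_A (mL/mg) the adsorption equilibrium constant; half-saturation is at
[E] = 1/K_A. `nanokin` extracts R from turbidity traces by ordinary least
squares on the initial window and fits (k_τ, K_A) by nonlinear least squares
seeded from the exact double-reciprocal linearization.

**Soluble-substrate and stability kinetics.** Michaelis–Menten fits for the
chromogenic pNPB esterase assay (v = V_max·S/(K_m+S), k_cat = V_max/E₀),
first-order thermal inactivation (A(t) = e^(−k_d·t), t_½ = ln2/k_d), and
descriptive pH/temperature activity profiles.

**Trajectory metrics.** Kabsch (SVD) optimal superposition with reflection
suppression, backbone RMSD time courses, per-residue Cα RMSF about the
superposed mean structure, and inter-atom distance series such as the
catalytic His–Ser distance of the Ser-His-Asp triad — with a multi-model
PDB/XYZ reader-writer and a `chain:resid:atomname` selection language.

Every input the analysis consumes can be produced by the seeded simulators
in `nanokin.synthetic`, so the whole chain is testable end to end with known
ground truth.

## Worked example

```python
import numpy as np
from nanokin import (ErosionScenario, simulate_turbidity_curves,
                     rates_from_curves, fit_saturation)

scenario = ErosionScenario(k_tau=4.1e-3, K_A=44.4,   # PET, 50 °C
                           noise_rel=0.0, n_replicates=1)
curves = simulate_turbidity_curves(scenario)          # τ(t) per [E]
rates = rates_from_curves(curves)                     # −d√(τ/τ₀)/dt per [E]
fit = fit_saturation(rates)
print(f"k_tau = {fit.k_tau*1e3:.2f}e-3 /min, K_A = {fit.K_A:.1f} mL/mg, "
      f"R^2 = {fit.r_squared:.4f}")
```

prints

```
k_tau = 4.10e-3 /min, K_A = 44.4 mL/mg, R^2 = 1.0000
```

i.e. on noise-free traces the full chain (simulation → √-normalization →
initial-rate regression → saturation fit) returns the generating constants
exactly: the saturating √-turbidity rate is 4.1×10⁻³ min⁻¹ and adsorption
half-saturates at 1/44.4 ≈ 0.023 mg/mL enzyme.

The same workflow runs from the shell:

```sh
nanokin simulate-turbidity --k-tau 4.1e-3 --ka 44.4 --noise-rel 0.03 \
        --seed 1 --out pet.csv
nanokin rates pet.csv --config pet.csv.conditions.yaml --out rates.csv
nanokin fit-saturation rates.csv --out fit.json
```

and `nanokin fit-mm`, `fit-decay`, `traj-rmsd`, `traj-rmsf`,
`traj-distance` and `run` (end-to-end with a YAML config) cover the rest.

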