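# Methods

## Erosion model for turbidimetric kinetics

Turbidity of a polyester nanoparticle suspension is treated as geometric
scattering: τ ∝ N·r², with the particle number N constant and the mean
radius r shrinking at a constant surface-erosion velocity while enzyme
covers the surface. Then √(τ/τ₀) = r/r₀ decreases linearly until the
particles are consumed, after which τ is clamped at exactly zero (a fully
hydrolyzed suspension). The fitted observable is therefore
R = −d√(τ/τ₀)/dt on the initial linear window, and the saturation model

    R([E]) = k_τ · K_A·[E] / (1 + K_A·[E])

is a Langmuir-type adsorption equilibrium: surface coverage θ =
K_A[E]/(1+K_A[E]) and R = k_τ·θ. k_τ carries units of min⁻¹ (the same
units the rate R is measured in), K_A of mL/mg, so K_A·[E] is
dimensionless with [E] in mg/mL — the package-wide canonical enzyme unit
(µg/mL inputs are converted at the I/O boundary, never silently inside).
Polydispersity, Mie scattering, and particle-number changes are outside the
model; the √-linearity of real traces is an approximation that holds for
the initial phase only, which is why a window policy exists at all.

A note on rate conventions: the saturating model is sometimes written as a
turbidity derivative dτ/dt, but the quantity actually regressed here is the
√-turbidity slope, consistent with k_τ's units of min⁻¹ on a normalized,
dimensionless ordinate. The two agree up to the factor 2τ₀·√(τ/τ₀) at
t = 0.

## Initial-rate estimation

y(t) = √(τ(t)/τ₀) is regressed on t by ordinary least squares; the rate is
−slope, floored at 0, with the usual slope standard error. Window policies:

- **fixed** (default): all samples with t ≤ t_max. Per-substrate defaults
  mirror the assay protocols — PCL: 15 min at 1-min sampling; PET: 60 min
  at 5-min sampling.
- **auto**: the longest prefix of ≥ 4 points whose linear fit has
  R² ≥ 0.98 (falling back, with a warning, to the best-R² prefix when none
  qualifies). Because R² degrades slowly, this rule can overrun a sharp
  depletion kink by a few samples and bias the slope slightly low; the
  fixed protocol windows are the default for exactly this reason.

Replicate traces at one enzyme concentration are averaged at the rate
level; the point SE is the SE of the replicate mean (single replicates fall
back to the slope SE).

## Saturation fitting

Nonlinear least squares (scipy's Levenberg–Marquardt / TRF via
`curve_fit`, xtol 1e-10) started from the exact double-reciprocal
linearization 1/R = 1/k_τ + 1/(k_τK_A)·(1/[E]) fitted by OLS on the
positive-rate points; if that degenerates (non-positive intercept/slope)
the start is k_τ⁰ = 1.5·max R, K_A⁰ = 1/median [E]. On noise-free data the
initializer is already exact, so recovery to relative 1e-6 is a structural
property, not a tuning outcome.

Points with [E] strictly above the concentration of the maximal observed
rate are excluded by default and recorded in the result: the model is
monotone in [E], while real assays show depressed rates when excess enzyme
crowds the particle surface beyond monolayer coverage. Exclusion can be
disabled. Fits are unweighted by default (duplicate-based error bars exist
but carry no stated weighting convention); optional 1/SE² weighting is
available. Reported uncertainties are 1-SE from the Gauss–Newton
covariance; R² is computed on the included points. Non-convergence returns
a result flagged `converged=False` rather than raising, so a multi-
condition pipeline can continue. Fold changes between two fits are reported
at full precision alongside a 2-significant-figure presentation rounding.

## Soluble-substrate and stability kinetics

Michaelis–Menten fits use the same pattern: Lineweaver–Burk initializer,
nonlinear refinement, warnings when the substrate grid does not bracket the
K_m estimate (saturated or linear-regime data). k_cat = V_max/E₀ only when
E₀ is supplied. Thermal inactivation is fitted as a single exponential
A(t) = e^(−k_d·t) — the minimal model for smooth monotone activity loss;
the amplitude is pinned at 1 because residual activities are normalized to
the unincubated control. A through-origin regression of ln A on t seeds a
one-parameter nonlinear refinement; k_d values indistinguishable from zero
(k_d·t_max < 1e-9) are snapped to 0 with t_½ = ∞. Two points suffice for
identifiability of the single parameter. Activity profiles over pH or
temperature are purely descriptive: normalization to the maximum, grid
argmax optimum, linear interpolation, no smoothing.

One esterase unit (U) is 1 µmol pNPB hydrolyzed per minute; conversion
between U/mg and k_cat requires an explicit molar mass
(`specific_activity_to_kcat`) and is never implied.

## Trajectory metrics

Superposition is the Kabsch algorithm: SVD of the cross-covariance of
centered coordinate sets with the sign of the smallest singular direction
corrected, so the rotation is always proper (det = +1, orthogonal to
1e-8). Collinear or coincident reference selections are rejected as
ill-posed. RMSD time courses superpose each frame onto the chosen reference
frame over the selection ("backbone" = N, CA, C, O) and evaluate RMSD over
that same selection. RMSF uses two superposition passes (align onto the raw
mean, recompute the mean, align again) and reports, per residue, the root
mean squared displacement of its selected atoms (default Cα) about their
time-averaged positions; a separate `align_selection` lets mobile atoms be
kept out of the alignment. Distances require atom specs that resolve
uniquely ("chain:resid:atomname" with wildcards); the catalytic His–Ser
distance convention is His Nε2 to Ser Oγ, the triad hydrogen-bond
geometry, overridable by selecting other atoms. Internal units are Å with
nm output on request.

The PDB dialect is deliberately narrow: ATOM records in MODEL/ENDMDL
blocks, altloc blank-or-'A', insertion codes kept inside the residue id
string, coordinates at the format's fixed 0.001 Å precision. PDB carries no
time axis, so frame times are synthesized at a user-given spacing; XYZ
files written by the package store the time on the comment line and round-
trip it.

## Synthetic data

The simulators generate exactly what the models assume, at the study's
assay conditions as defaults: PET erosion scenarios run 60 min at 5-min
sampling on an 8-point enzyme grid up to 0.08 mg/mL (PCL: 15 min, 1-min,
up to 0.03 mg/mL), duplicate determinations, 3% relative multiplicative
Gaussian noise on turbidity and rates (plate-reader-like), additive noise
on activity fractions (clipped to [0, 1.05]). τ₀ defaults to 0.4 A600, a
typical suspension absorbance; all analyses are scale-invariant in τ₀, so
the choice is cosmetic. An optional crowding factor 1/(1+([E]/E_inh)^h)
emulates the high-[E] rate decline attributed to unproductive enzyme
excess; it is off by default and applied smoothly at all [E] (a hard
threshold would make R([E]) discontinuous). Trajectory scenarios add
per-atom Gaussian displacements (per coordinate, so an isotropic atom has
RMSF σ√3) to a reference structure, optionally carried through a uniform
random rotation and a Gaussian translation per frame; atoms are labelled as
consecutive Cα/glycine so standard selections resolve.

Every simulator takes a mandatory-defaulted integer seed and is
bit-reproducible for a fixed seed. What the generators do **not** emulate:
baseline drift and heteroscedastic plate-reader noise, polydisperse
particle populations, enzyme inactivation during the assay, correlated
(non-white) trajectory dynamics, or solvent/periodic-boundary artifacts.
Passing recovery tests therefore demonstrates correctness of the estimation
chain under its own assumptions, not robustness to every failure mode of
real data.

## Numerical choices and degenerate inputs

- Tolerances: curve_fit xtol 1e-10 (saturation, MM), 1e-12 (decay);
  noise-free recovery asserted at relative 1e-6.
- Exclusion tie-break: when several concentrations share the maximal rate,
  the largest is kept as the cutoff so exclusion is minimal.
- Supra-maximal exclusion, weighting, and window policy are all explicit
  options logged per run; the pipeline records them in its JSON report
  together with a config hash and seed for provenance.
- Degenerate inputs fail loudly with the offending field named: zero
  initial turbidity, identical time stamps, < 3 distinct concentrations,
  all-zero rates (K_A unidentifiable), non-positive activity fractions,
  collinear superposition references, ambiguous atom specs.
- Monte-Carlo problem sizes used in the test suite and acceptance script —
  200 replicates for median-recovery checks, 10⁴ frames for RMSF, 10⁴
  draws for noise calibration — were chosen as the smallest sizes at which
  the Monte-Carlo error is comfortably below the tolerance being checked.

## Known limitations

- The adsorption-saturation fit treats rate points as independent and
  homoscedastic unless SE weights are supplied; no errors-in-variables
  treatment of enzyme concentration.
- The single-exponential inactivation model cannot represent biphasic or
  lag-phase inactivation; fits to such data will show structured residuals
  (inspect r_squared).
- The auto window rule is R²-greedy and can overrun sharp kinks (see
  above); prefer fixed protocol windows when the protocol is known.
- The PDB writer emits coordinate records only (no CRYST1, no elements,
  occupancy/B-factor fixed), which is sufficient for round-tripping
  trajectories but not for deposition-grade files.
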