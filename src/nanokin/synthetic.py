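"""Forward simulators for every input the analysis chain consumes.

Each scenario dataclass captures one study condition (turbidimetric
nanoparticle erosion, soluble-substrate Michaelis-Menten assay, thermal
inactivation, or an atomic trajectory) together with its noise model and a
mandatory RNG seed, so that every downstream stage can be exercised with
data of known ground truth.

Turbidity traces follow a shrinking-sphere / geometric-scattering erosion
model: with turbidity proportional to total particle cross-section (N*r^2 at
constant particle number), constant surface erosion makes sqrt(tau/tau0)
decrease linearly at rate R([E]) = k_tau*K_A*[E]/(1+K_A*[E]) until the
suspension is fully hydrolyzed, after which turbidity is clamped at zero.
Noise is multiplicative Gaussian on turbidity and on rates (plate-reader
behavior) and additive on residual-activity fractions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import require
from .turbidity import Condition, RateDataset, RatePoint, TurbidityCurve, predict_rate
from .trajectory import Trajectory

__all__ = [
    "CrowdingModel",
    "ErosionScenario",
    "MMScenario",
    "DecayScenario",
    "TrajectoryScenario",
    "simulate_turbidity_curves",
    "simulate_rate_dataset",
    "simulate_mm_dataset",
    "simulate_decay_dataset",
    "simulate_trajectory",
]

# Default enzyme-concentration grids (mg/mL): the assay ranges of the PET
# (up to 0.08 mg/mL) and PCL (up to 0.03 mg/mL) nanoparticle experiments.
PET_ENZYME_GRID = (0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.065, 0.08)
PCL_ENZYME_GRID = (0.002, 0.005, 0.008, 0.012, 0.016, 0.02, 0.025, 0.03)


@dataclass(frozen=True)
class CrowdingModel:
    """Optional high-[E] inhibition: surfaces crowded with excess enzyme.

    The effective rate is R([E]) / (1 + ([E]/e_inh)**hill); the factor is
    ~1 well below the threshold e_inh and halves the rate at [E] = e_inh.
    """

    e_inh: float  # mg/mL
    hill: float = 2.0

    def __post_init__(self) -> None:
        require(self.e_inh > 0, "e_inh", "must be > 0")
        require(self.hill > 0, "hill", "must be > 0")

    def factor(self, enzyme_conc):
        E = np.asarray(enzyme_conc, dtype=float)
        return 1.0 / (1.0 + (E / self.e_inh) ** self.hill)


@dataclass(frozen=True)
class ErosionScenario:
    """Turbidimetric nanoparticle-erosion assay conditions.

    Defaults are the PET assay at 50 degC: 60 min at 5-min sampling,
    duplicate determinations, 3% relative turbidity noise.
    """

    k_tau: float = 4.1e-3  # 1/min
    K_A: float = 44.4  # mL/mg
    enzyme_concs: tuple[float, ...] = PET_ENZYME_GRID  # mg/mL
    tau0: float = 0.4  # A600 of the particle suspension
    duration: float = 60.0  # min
    dt: float = 5.0  # min
    noise_rel: float = 0.03
    seed: int = 0
    crowding: CrowdingModel | None = None
    n_replicates: int = 2
    substrate: str = "PET"
    temperature: float = 50.0  # degC

    def __post_init__(self) -> None:
        require(self.k_tau > 0, "k_tau", "must be > 0")
        require(self.K_A > 0, "K_A", "must be > 0")
        require(self.tau0 > 0, "tau0", "must be > 0")
        require(self.dt > 0, "dt", "must be > 0")
        require(self.duration >= 2 * self.dt, "duration", "must be >= 2*dt")
        require(self.noise_rel >= 0, "noise_rel", "must be >= 0")
        require(len(self.enzyme_concs) > 0, "enzyme_concs", "must not be empty")
        require(
            all(e >= 0 for e in self.enzyme_concs), "enzyme_concs", "must all be >= 0"
        )
        require(self.n_replicates >= 1, "n_replicates", "must be >= 1")

    def rate(self, enzyme_conc):
        """Noise-free initial sqrt-turbidity rate R([E]) incl. crowding."""
        E = np.asarray(enzyme_conc, dtype=float)
        R = np.where(E > 0, predict_rate(self.k_tau, self.K_A, np.maximum(E, 0)), 0.0)
        if self.crowding is not None:
            R = R * self.crowding.factor(E)
        return float(R) if np.isscalar(enzyme_conc) else R


@dataclass(frozen=True)
class MMScenario:
    """Soluble-substrate (pNPB) Michaelis-Menten assay conditions."""

    K_m: float = 88.8  # uM
    k_cat: float = 2.3  # 1/s
    E0: float = 0.1  # uM enzyme
    substrate_concs: tuple[float, ...] = tuple(np.geomspace(10.0, 1000.0, 10))
    noise_rel: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.K_m > 0, "K_m", "must be > 0")
        require(self.k_cat > 0, "k_cat", "must be > 0")
        require(self.E0 > 0, "E0", "must be > 0")
        require(len(self.substrate_concs) > 0, "substrate_concs", "must not be empty")
        require(
            all(s > 0 for s in self.substrate_concs),
            "substrate_concs",
            "must be strictly positive",
        )
        require(self.noise_rel >= 0, "noise_rel", "must be >= 0")


@dataclass(frozen=True)
class DecayScenario:
    """First-order thermal-inactivation time course.

    Default k_d = ln(2.5)/60 per min reproduces 40% residual activity after
    60 min, the published behavior of the less stable hydrolase at 50 degC.
    """

    k_d: float = float(np.log(2.5) / 60.0)  # 1/min
    times: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0)  # min
    noise_abs: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.k_d >= 0, "k_d", "must be >= 0")
        require(len(self.times) > 0, "times", "must not be empty")
        t = np.asarray(self.times, dtype=float)
        require(bool(np.all(t >= 0)), "times", "must be non-negative")
        require(bool(np.all(np.diff(t) > 0)), "times", "must be increasing")
        require(self.noise_abs >= 0, "noise_abs", "must be >= 0")


@dataclass(frozen=True)
class TrajectoryScenario:
    """Rigid-body-perturbed atomic trajectory with prescribed fluctuations.

    A stand-in for an MD trajectory: each frame is the reference structure
    plus independent per-atom Gaussian displacements of s.d. per_atom_sigma
    (per coordinate, Angstrom), optionally carried through a random rigid
    rotation + translation per frame.
    """

    n_atoms: int = 50
    n_frames: int = 100
    reference_coords: np.ndarray | None = None  # (n_atoms, 3) Angstrom
    per_atom_sigma: float | np.ndarray = 0.5  # Angstrom, scalar or per atom
    rigid_motion: bool = True
    dt_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.n_atoms >= 1, "n_atoms", "must be >= 1")
        if self.rigid_motion:
            require(self.n_atoms >= 3, "n_atoms", "must be >= 3 with rigid_motion")
        require(self.n_frames >= 1, "n_frames", "must be >= 1")
        sigma = np.asarray(self.per_atom_sigma, dtype=float)
        require(bool(np.all(sigma >= 0)), "per_atom_sigma", "must be >= 0 elementwise")
        if self.reference_coords is not None:
            ref = np.asarray(self.reference_coords, dtype=float)
            require(
                ref.shape == (self.n_atoms, 3),
                "reference_coords",
                f"must have shape ({self.n_atoms}, 3)",
            )
        require(self.dt_ns > 0, "dt_ns", "must be > 0")


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _erosion_trace(tau0: float, rate: float, times: np.ndarray) -> np.ndarray:
    """tau(t) = tau0 * max(0, 1 - R t)^2: linear sqrt decay, clamped at full
    hydrolysis."""
    return tau0 * np.clip(1.0 - rate * times, 0.0, None) ** 2


def simulate_turbidity_curves(scenario: ErosionScenario) -> list[TurbidityCurve]:
    """Simulate one turbidity trace per enzyme concentration and replicate.

    Multiplicative Gaussian noise (1 + eps), eps ~ N(0, noise_rel), is
    applied per sample; values are clamped at >= 0 and the t=0 sample kept
    strictly positive so every trace is a valid curve.  Bit-identical for a
    fixed seed.
    """
    rng = np.random.default_rng(scenario.seed)
    n_steps = int(round(scenario.duration / scenario.dt))
    times = np.arange(n_steps + 1) * scenario.dt
    curves = []
    for E in scenario.enzyme_concs:
        base = _erosion_trace(scenario.tau0, scenario.rate(E), times)
        for rep in range(scenario.n_replicates):
            tau = base.copy()
            if scenario.noise_rel > 0:
                tau = tau * (1.0 + rng.normal(0.0, scenario.noise_rel, times.shape))
            tau = np.clip(tau, 0.0, None)
            tau[0] = max(tau[0], scenario.tau0 * 1e-9)
            curves.append(
                TurbidityCurve(
                    times=times.copy(),
                    turbidity=tau,
                    condition=Condition(
                        enzyme_conc=E,
                        substrate=scenario.substrate,
                        temperature=scenario.temperature,
                        replicate=rep,
                    ),
                )
            )
    return curves


def simulate_rate_dataset(scenario: ErosionScenario) -> RateDataset:
    """Emit (E, R(E)+noise) points directly, bypassing curve synthesis.

    Replicate rates carry multiplicative noise; the point value is the
    replicate mean with its standard error.  Noise-free output equals R(E)
    exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    points = []
    for E in scenario.enzyme_concs:
        true_rate = scenario.rate(E)
        reps = np.full(scenario.n_replicates, true_rate)
        if scenario.noise_rel > 0:
            reps = reps * (1.0 + rng.normal(0.0, scenario.noise_rel, reps.shape))
        reps = np.clip(reps, 0.0, None)
        n = scenario.n_replicates
        se = float(reps.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        points.append(RatePoint(E, float(reps.mean()), se, n))
    return RateDataset(
        points=points, substrate=scenario.substrate, temperature=scenario.temperature
    )


def simulate_mm_dataset(scenario: MMScenario) -> pd.DataFrame:
    """Michaelis-Menten velocities v = k_cat*E0*S/(K_m+S) with
    multiplicative noise.  Columns: substrate_conc_uM, velocity_uM_per_s."""
    rng = np.random.default_rng(scenario.seed)
    S = np.asarray(scenario.substrate_concs, dtype=float)
    v = scenario.k_cat * scenario.E0 * S / (scenario.K_m + S)
    if scenario.noise_rel > 0:
        v = v * (1.0 + rng.normal(0.0, scenario.noise_rel, S.shape))
    v = np.clip(v, 0.0, None)
    return pd.DataFrame({"substrate_conc_uM": S, "velocity_uM_per_s": v})


def simulate_decay_dataset(scenario: DecayScenario) -> pd.DataFrame:
    """Residual activity A(t) = exp(-k_d t) with additive noise, clipped to
    [0, 1.05].  Columns: time_min, residual_activity."""
    rng = np.random.default_rng(scenario.seed)
    t = np.asarray(scenario.times, dtype=float)
    A = np.exp(-scenario.k_d * t)
    if scenario.noise_abs > 0:
        A = A + rng.normal(0.0, scenario.noise_abs, t.shape)
    A = np.clip(A, 0.0, 1.05)
    return pd.DataFrame({"time_min": t, "residual_activity": A})


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def simulate_trajectory(scenario: TrajectoryScenario) -> Trajectory:
    """Simulate a fluctuating trajectory around a reference structure.

    Frame f is Rot_f @ (ref + eps) + trans_f with eps per-atom Gaussian of
    s.d. per_atom_sigma per coordinate (rotation/translation omitted when
    rigid_motion is off).  Atoms are labelled as consecutive C-alpha atoms
    (one glycine residue per atom) so standard selections resolve.
    """
    rng = np.random.default_rng(scenario.seed)
    n, F = scenario.n_atoms, scenario.n_frames
    if scenario.reference_coords is not None:
        ref = np.asarray(scenario.reference_coords, dtype=float)
    else:
        # self-avoiding-ish random coil: cumulative random steps of ~3.8 A
        steps = rng.normal(scale=3.8 / np.sqrt(3.0), size=(n, 3))
        ref = np.cumsum(steps, axis=0)
    sigma = np.broadcast_to(
        np.asarray(scenario.per_atom_sigma, dtype=float).reshape(-1, 1), (n, 3)
    ) if np.ndim(scenario.per_atom_sigma) else np.full((n, 3), float(scenario.per_atom_sigma))

    coords = np.empty((F, n, 3))
    for f in range(F):
        frame = ref + rng.normal(0.0, 1.0, (n, 3)) * sigma
        if scenario.rigid_motion:
            rot = _random_rotation(rng)
            trans = rng.normal(0.0, 5.0, 3)
            frame = frame @ rot.T + trans
        coords[f] = frame
    return Trajectory(
        coords=coords,
        frame_times=np.arange(F) * scenario.dt_ns,
        atom_names=["CA"] * n,
        residue_ids=[str(i + 1) for i in range(n)],
        residue_names=["GLY"] * n,
        chains=["A"] * n,
    )
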