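"""Turbidimetric degradation kinetics of polyester nanoparticles.

The hydrolysis of an insoluble polyester (PCL or PET) dispersed as a
nanoparticle suspension is followed by the decrease of turbidity at 600 nm.
Under a geometric-scattering approximation (turbidity proportional to the
total particle cross-section, N·r² at constant particle number N) and
constant surface erosion, the square root of the normalized turbidity,
y(t) = sqrt(tau(t)/tau(0)), decreases linearly during the initial phase of
the reaction.  The initial rate R = -dy/dt saturates hyperbolically in the
enzyme concentration [E]:

    R([E]) = k_tau * K_A * [E] / (1 + K_A * [E])

where k_tau (1/min) is the hydrolysis rate constant based on the turbidity
change — the saturating value of R — and K_A (mL/mg) is the adsorption
equilibrium constant coupling enzyme concentration to surface coverage.
Half-saturation occurs at [E] = 1/K_A.  This module transforms turbidity
traces to initial rates and fits the saturation model.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateInputError, FitError, ValidationError, require

__all__ = [
    "Condition",
    "TurbidityCurve",
    "RatePoint",
    "RateDataset",
    "SaturationFit",
    "FoldChange",
    "WindowPolicy",
    "InitialRate",
    "predict_rate",
    "sqrt_normalize",
    "estimate_initial_rate",
    "rates_from_curves",
    "fit_saturation",
    "fold_change",
    "round_sig",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """Assay condition attached to a turbidity trace.

    enzyme_conc is in mg/mL (the package-wide canonical unit, so that
    K_A * [E] is dimensionless with K_A in mL/mg).
    """

    enzyme_conc: float
    substrate: str = "PET"
    temperature: float = 50.0
    replicate: int = 0

    def __post_init__(self) -> None:
        require(self.enzyme_conc >= 0, "enzyme_conc", "must be >= 0 mg/mL")

    @property
    def key(self) -> str:
        return f"{self.substrate}@{self.temperature:g}C"


@dataclass
class TurbidityCurve:
    """A time-stamped turbidity trace (A600) with its assay condition."""

    times: np.ndarray  # minutes, strictly increasing
    turbidity: np.ndarray  # absorbance units, >= 0
    condition: Condition

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.turbidity = np.asarray(self.turbidity, dtype=float)
        require(self.times.ndim == 1, "times", "must be one-dimensional")
        require(
            self.times.shape == self.turbidity.shape,
            "turbidity",
            "must have the same length as times",
        )
        require(self.times.size >= 2, "times", "need at least two samples")
        require(bool(np.all(np.diff(self.times) > 0)), "times", "must be strictly increasing")
        require(bool(np.all(self.turbidity >= 0)), "turbidity", "must be non-negative")
        require(np.isfinite(self.turbidity).all(), "turbidity", "must be finite")
        if self.turbidity[0] <= 0:
            raise DegenerateInputError(
                "turbidity: initial value must be > 0 for sqrt-normalization"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RatePoint:
    """One (enzyme concentration, initial rate) observation."""

    enzyme_conc: float  # mg/mL
    rate: float  # 1/min, -d sqrt(tau/tau0)/dt on the initial window
    rate_se: float = 0.0
    n_replicates: int = 1


@dataclass
class RateDataset:
    """Initial degradation rates as a function of enzyme concentration."""

    points: list[RatePoint]
    substrate: str = "PET"
    temperature: float = 50.0

    def __post_init__(self) -> None:
        require(len(self.points) >= 1, "points", "must not be empty")
        for p in self.points:
            require(p.enzyme_conc >= 0, "enzyme_conc", "must be >= 0")
            require(p.rate >= 0, "rate", "must be >= 0")

    @property
    def enzyme_concs(self) -> np.ndarray:
        return np.array([p.enzyme_conc for p in self.points])

    @property
    def rates(self) -> np.ndarray:
        return np.array([p.rate for p in self.points])

    @property
    def rate_ses(self) -> np.ndarray:
        return np.array([p.rate_se for p in self.points])


@dataclass
class SaturationFit:
    """Result of fitting R([E]) = k_tau*K_A*[E]/(1+K_A*[E])."""

    k_tau: float  # 1/min
    K_A: float  # mL/mg
    se_k_tau: float
    se_K_A: float
    covariance: np.ndarray  # 2x2, parameter order (k_tau, K_A)
    r_squared: float
    n_points_used: int
    excluded_points: list[RatePoint]
    converged: bool
    message: str = ""

    def predict(self, enzyme_conc):
        return predict_rate(self.k_tau, self.K_A, enzyme_conc)

    def to_dict(self) -> dict:
        return {
            "k_tau_per_min": self.k_tau,
            "K_A_mL_per_mg": self.K_A,
            "se_k_tau": self.se_k_tau,
            "se_K_A": self.se_K_A,
            "covariance": np.asarray(self.covariance).tolist(),
            "r_squared": self.r_squared,
            "n_points_used": self.n_points_used,
            "excluded_points": [
                {"enzyme_conc": p.enzyme_conc, "rate": p.rate} for p in self.excluded_points
            ],
            "converged": self.converged,
            "message": self.message,
        }


@dataclass(frozen=True)
class FoldChange:
    """Elementwise parameter ratios fit_b / fit_a."""

    k_tau_ratio: float
    K_A_ratio: float

    @property
    def k_tau_ratio_2sf(self) -> float:
        return round_sig(self.k_tau_ratio, 2)

    @property
    def K_A_ratio_2sf(self) -> float:
        return round_sig(self.K_A_ratio, 2)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def predict_rate(k_tau: float, K_A: float, enzyme_conc):
    """Saturation-model rate R([E]) = k_tau*K_A*[E]/(1+K_A*[E]) in 1/min.

    Strictly increasing in [E], bounded above by k_tau, with
    R(1/K_A) = k_tau/2.
    """
    require(k_tau > 0, "k_tau", "must be > 0")
    require(K_A > 0, "K_A", "must be > 0")
    E = np.asarray(enzyme_conc, dtype=float)
    require(bool(np.all(E >= 0)), "enzyme_conc", "must be >= 0")
    rate = k_tau * K_A * E / (1.0 + K_A * E)
    return float(rate) if np.isscalar(enzyme_conc) else rate


def sqrt_normalize(curve: TurbidityCurve) -> np.ndarray:
    """Return y(t) = sqrt(tau(t)/tau(0)); y[0] == 1 exactly.

    Scale-invariant: multiplying the turbidity trace by any c > 0 leaves
    the output unchanged.
    """
    tau0 = curve.turbidity[0]
    if tau0 <= 0:
        raise DegenerateInputError("turbidity: initial value is zero")
    y = np.sqrt(curve.turbidity / tau0)
    y[0] = 1.0
    return y


@dataclass(frozen=True)
class WindowPolicy:
    """Selection of the initial linear window of y(t)=sqrt(tau/tau0).

    mode "fixed": use all samples with t <= t_max (the assay protocols:
    15 min for PCL, 60 min for PET).  mode "auto": the longest prefix with
    at least min_points samples whose linear fit has R^2 >= r2_min; if no
    prefix qualifies the best-R^2 prefix is used.
    """

    mode: str = "fixed"
    t_max: float | None = 60.0
    r2_min: float = 0.98
    min_points: int = 4

    def __post_init__(self) -> None:
        require(self.mode in ("fixed", "auto"), "mode", "must be 'fixed' or 'auto'")
        require(self.min_points >= 4, "min_points", "must be >= 4")
        if self.mode == "fixed":
            require(self.t_max is not None and self.t_max > 0, "t_max", "must be > 0")

    @staticmethod
    def for_substrate(substrate: str) -> "WindowPolicy":
        sub = substrate.upper()
        if sub == "PCL":
            return WindowPolicy(mode="fixed", t_max=15.0)
        if sub == "PET":
            return WindowPolicy(mode="fixed", t_max=60.0)
        return WindowPolicy(mode="auto", t_max=None)


@dataclass(frozen=True)
class InitialRate:
    """Initial degradation rate with its OLS standard error."""

    rate: float  # 1/min, reported non-negative
    se: float
    window_used: tuple[float, float, int]  # (t_start, t_end, n_points)
    r_squared: float


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, slope SE and R^2 of an ordinary least-squares line."""
    n = t.size
    tbar, ybar = t.mean(), y.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0.0:
        raise ValidationError("times: all sample times identical, slope undefined")
    slope = float(((t - tbar) * (y - ybar)).sum() / sxx)
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    rss = float((resid**2).sum())
    tss = float(((y - ybar) ** 2).sum())
    dof = n - 2
    se = math.sqrt(rss / dof / sxx) if dof > 0 else 0.0
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return slope, intercept, se, r2


def estimate_initial_rate(
    curve: TurbidityCurve, window: WindowPolicy | None = None
) -> InitialRate:
    """Initial degradation rate -d sqrt(tau/tau0)/dt on the selected window.

    The rate is the negative OLS slope of y(t) = sqrt(tau/tau0) over the
    initial window, reported non-negative (a rising trace yields rate 0);
    the SE is the standard error of the slope.
    """
    if window is None:
        window = WindowPolicy.for_substrate(curve.condition.substrate)
    y = sqrt_normalize(curve)
    t = curve.times

    if window.mode == "fixed":
        mask = t <= window.t_max + 1e-12
        idx = int(mask.sum())
        if idx < window.min_points:
            raise ValidationError(
                f"window: only {idx} samples with t <= {window.t_max} min, "
                f"need >= {window.min_points}"
            )
        n_used = idx
        slope, _, se, r2 = _ols_line(t[:n_used], y[:n_used])
    else:  # auto: longest acceptable prefix
        if t.size < window.min_points:
            raise ValidationError(
                f"window: curve has {t.size} samples, need >= {window.min_points}"
            )
        best = None  # (n, slope, se, r2)
        fallback = None
        for n in range(window.min_points, t.size + 1):
            slope, _, se, r2 = _ols_line(t[:n], y[:n])
            if fallback is None or r2 > fallback[3]:
                fallback = (n, slope, se, r2)
            if r2 >= window.r2_min:
                best = (n, slope, se, r2)
        if best is None:
            best = fallback
            warnings.warn(
                "no prefix reached the linearity threshold "
                f"R^2 >= {window.r2_min}; using best prefix (R^2 = {best[3]:.4f})",
                stacklevel=2,
            )
        n_used, slope, se, r2 = best

    return InitialRate(
        rate=max(-slope, 0.0),
        se=se,
        window_used=(float(t[0]), float(t[n_used - 1]), int(n_used)),
        r_squared=r2,
    )


def rates_from_curves(
    curves: Sequence[TurbidityCurve], window: WindowPolicy | None = None
) -> RateDataset:
    """Collapse turbidity traces to a rate-vs-enzyme-concentration dataset.

    Curves must share one substrate and temperature.  Replicates at the
    same enzyme concentration are averaged; the point SE is the standard
    error of the replicate mean (falling back to the slope SE for single
    replicates).
    """
    require(len(curves) >= 1, "curves", "must not be empty")
    keys = {(c.condition.substrate, c.condition.temperature) for c in curves}
    if len(keys) != 1:
        raise ValidationError(
            f"curves: mixed substrate/temperature conditions {sorted(keys)}; "
            "group before rate extraction"
        )
    substrate, temperature = next(iter(keys))

    by_conc: dict[float, list[InitialRate]] = {}
    for c in curves:
        by_conc.setdefault(c.condition.enzyme_conc, []).append(
            estimate_initial_rate(c, window)
        )

    points = []
    for conc in sorted(by_conc):
        ests = by_conc[conc]
        rates = np.array([e.rate for e in ests])
        n = len(ests)
        if n > 1:
            se = float(rates.std(ddof=1) / math.sqrt(n))
        else:
            se = ests[0].se
        points.append(RatePoint(conc, float(rates.mean()), se, n))
    return RateDataset(points=points, substrate=substrate, temperature=temperature)


def _saturation_model(E, k_tau, K_A):
    return k_tau * K_A * E / (1.0 + K_A * E)


def _double_reciprocal_init(E: np.ndarray, R: np.ndarray) -> tuple[float, float] | None:
    """Initial values from OLS on 1/R = 1/k_tau + 1/(k_tau*K_A) * 1/E."""
    mask = (E > 0) & (R > 0)
    if mask.sum() < 2:
        return None
    x, y = 1.0 / E[mask], 1.0 / R[mask]
    slope, intercept, _, _ = _ols_line(x, y)
    if intercept <= 0 or slope <= 0:
        return None
    return 1.0 / intercept, intercept / slope


def fit_saturation(
    data: RateDataset,
    *,
    weighted: bool = False,
    exclude_supramaximal: bool = True,
    xtol: float = 1e-10,
) -> SaturationFit:
    """Weighted nonlinear least-squares fit of the adsorption-saturation model.

    Points with enzyme concentration strictly above the concentration of the
    maximal observed rate are excluded by default: the model is monotone in
    [E], while excess enzyme beyond monolayer surface coverage depresses the
    observed rate.  Exclusions are recorded in the result.  Initial values
    come from the double-reciprocal linearization; SEs from the Gauss-Newton
    covariance approximation.
    """
    E_all, R_all = data.enzyme_concs, data.rates
    SE_all = data.rate_ses

    excluded: list[RatePoint] = []
    used = np.ones(E_all.size, dtype=bool)
    if exclude_supramaximal and E_all.size:
        max_rate = R_all.max()
        # break ties toward the largest E so exclusion is minimal
        e_at_max = E_all[R_all == max_rate].max()
        used = E_all <= e_at_max
        excluded = [data.points[i] for i in np.flatnonzero(~used)]

    E, R, SE = E_all[used], R_all[used], SE_all[used]
    if np.unique(E).size < 3:
        raise FitError(
            f"need >= 3 distinct enzyme concentrations after exclusions, have {np.unique(E).size}"
        )
    if np.all(R == 0):
        raise FitError("all rates are zero: K_A is unidentifiable")

    p0 = _double_reciprocal_init(E, R)
    if p0 is None:
        p0 = (1.5 * float(R.max()), 1.0 / float(np.median(E[E > 0])))

    sigma = None
    absolute_sigma = False
    if weighted:
        if np.any(SE <= 0):
            raise FitError("weighted fit requires strictly positive rate SEs")
        sigma = SE
        absolute_sigma = True

    try:
        popt, pcov = curve_fit(
            _saturation_model,
            E,
            R,
            p0=p0,
            sigma=sigma,
            absolute_sigma=absolute_sigma,
            xtol=xtol,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return SaturationFit(
            k_tau=float("nan"),
            K_A=float("nan"),
            se_k_tau=float("nan"),
            se_K_A=float("nan"),
            covariance=np.full((2, 2), np.nan),
            r_squared=float("nan"),
            n_points_used=int(E.size),
            excluded_points=excluded,
            converged=False,
            message=str(exc),
        )

    k_tau, K_A = float(popt[0]), float(popt[1])
    pred = _saturation_model(E, *popt)
    rss = float(((R - pred) ** 2).sum())
    tss = float(((R - R.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return SaturationFit(
        k_tau=k_tau,
        K_A=K_A,
        se_k_tau=float(ses[0]),
        se_K_A=float(ses[1]),
        covariance=np.asarray(pcov),
        r_squared=max(0.0, min(1.0, r2)),
        n_points_used=int(E.size),
        excluded_points=excluded,
        converged=k_tau > 0 and K_A > 0,
        message="",
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (presentation convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fold_change(fit_a: SaturationFit, fit_b: SaturationFit) -> FoldChange:
    """Parameter ratios fit_b/fit_a (e.g. enzyme B relative to enzyme A)."""
    require(fit_a.converged, "fit_a", "must have converged")
    require(fit_b.converged, "fit_b", "must have converged")
    if fit_a.k_tau == 0 or fit_a.K_A == 0:
        raise ValidationError("fit_a: zero parameter in denominator")
    return FoldChange(
        k_tau_ratio=fit_b.k_tau / fit_a.k_tau,
        K_A_ratio=fit_b.K_A / fit_a.K_A,
    )
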