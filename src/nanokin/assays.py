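"""Soluble-substrate kinetics and stability summaries.

Michaelis-Menten fits for the chromogenic pNPB esterase assay
(v = V_max*S/(K_m+S), k_cat = V_max/E0), first-order thermal-inactivation
fits of residual-activity time courses (A(t) = exp(-k_d*t),
t_1/2 = ln2/k_d), and descriptive pH/temperature activity profiles.

Unit convention: one unit (U) of esterase activity hydrolyzes 1 umol pNPB
per minute.  Converting between specific activity (U/mg) and k_cat requires
a molar mass and is never done silently.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError, require

__all__ = [
    "MMFit",
    "DecayFit",
    "ActivityProfile",
    "fit_michaelis_menten",
    "fit_decay",
    "profile_summary",
    "specific_activity_to_kcat",
]


@dataclass
class MMFit:
    """Michaelis-Menten fit result.  Parameter order (V_max, K_m)."""

    K_m: float  # uM
    V_max: float  # uM/s
    k_cat: float | None  # 1/s, V_max/E0 when E0 given
    se_K_m: float
    se_V_max: float
    se_k_cat: float | None
    covariance: np.ndarray  # 2x2 over (V_max, K_m)
    r_squared: float
    converged: bool
    warnings: list[str]

    def predict(self, S):
        return self.V_max * np.asarray(S, float) / (self.K_m + np.asarray(S, float))

    def to_dict(self) -> dict:
        return {
            "K_m_uM": self.K_m,
            "V_max_uM_per_s": self.V_max,
            "k_cat_per_s": self.k_cat,
            "se_K_m": self.se_K_m,
            "se_V_max": self.se_V_max,
            "se_k_cat": self.se_k_cat,
            "covariance": np.asarray(self.covariance).tolist(),
            "r_squared": self.r_squared,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


@dataclass
class DecayFit:
    """First-order inactivation fit result; half_life = ln2/k_d (inf at k_d=0)."""

    k_d: float  # 1/min
    half_life: float  # min
    se_k_d: float
    r_squared: float

    def predict(self, t):
        return np.exp(-self.k_d * np.asarray(t, float))

    def to_dict(self) -> dict:
        return {
            "k_d_per_min": self.k_d,
            "half_life_min": self.half_life,
            "se_k_d": self.se_k_d,
            "r_squared": self.r_squared,
        }


@dataclass
class ActivityProfile:
    """Relative-activity profile over pH or temperature (descriptive only)."""

    x: np.ndarray
    activity: np.ndarray  # normalized, max = 1
    optimum: float

    def fraction_at(self, x0: float) -> float:
        """Linearly interpolated relative activity at x0 (within the grid)."""
        require(self.x[0] <= x0 <= self.x[-1], "x0", "outside the measured grid")
        return float(np.interp(x0, self.x, self.activity))


def _mm_model(S, V_max, K_m):
    return V_max * S / (K_m + S)


def _lineweaver_burk_init(S: np.ndarray, v: np.ndarray) -> tuple[float, float] | None:
    """(V_max, K_m) from OLS on 1/v = 1/V_max + (K_m/V_max)*(1/S)."""
    mask = (S > 0) & (v > 0)
    if mask.sum() < 2:
        return None
    x, y = 1.0 / S[mask], 1.0 / v[mask]
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        return None
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    intercept = ybar - slope * xbar
    if intercept <= 0:
        return None
    V_max = 1.0 / intercept
    K_m = slope * V_max
    if K_m <= 0:
        K_m = float(np.median(S[mask]))
    return V_max, K_m


def fit_michaelis_menten(S, v, E0: float | None = None, *, xtol: float = 1e-10) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Requires >= 4 points with >= 3 distinct substrate concentrations.
    Initial values come from the Lineweaver-Burk double-reciprocal
    regression.  Identifiability warnings are attached when the data do not
    bracket K_m (all S far above or far below the estimate).
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    require(S.shape == v.shape and S.ndim == 1, "v", "S and v must be equal-length 1-D")
    require(bool(np.all(S > 0)), "S", "substrate concentrations must be > 0")
    require(bool(np.all(v >= 0)), "v", "velocities must be >= 0")
    if S.size < 4:
        raise ValidationError(f"S: need >= 4 points, have {S.size}")
    if np.unique(S).size < 3:
        raise ValidationError("S: need >= 3 distinct substrate concentrations")

    p0 = _lineweaver_burk_init(S, v)
    if p0 is None:
        p0 = (float(v.max()) * 1.2 or 1.0, float(np.median(S)))

    msgs: list[str] = []
    try:
        popt, pcov = curve_fit(
            _mm_model, S, v, p0=p0, xtol=xtol, ftol=1e-14, gtol=1e-14, maxfev=20000
        )
        converged = True
    except (RuntimeError, ValueError) as exc:
        return MMFit(
            K_m=float("nan"), V_max=float("nan"), k_cat=None,
            se_K_m=float("nan"), se_V_max=float("nan"), se_k_cat=None,
            covariance=np.full((2, 2), np.nan), r_squared=float("nan"),
            converged=False, warnings=[str(exc)],
        )
    V_max, K_m = float(popt[0]), float(popt[1])
    if K_m < S.min() / 20:
        msgs.append(
            "K_m estimate far below the smallest substrate concentration; "
            "data are saturated and K_m is weakly identified"
        )
    elif K_m > S.max() * 20:
        msgs.append(
            "K_m estimate far above the largest substrate concentration; "
            "data are in the linear regime and V_max/K_m only is identified"
        )
    pred = _mm_model(S, *popt)
    rss = float(((v - pred) ** 2).sum())
    tss = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    k_cat = se_k_cat = None
    if E0 is not None:
        require(E0 > 0, "E0", "must be > 0")
        k_cat = V_max / E0
        se_k_cat = float(ses[0]) / E0
    return MMFit(
        K_m=K_m, V_max=V_max, k_cat=k_cat,
        se_K_m=float(ses[1]), se_V_max=float(ses[0]), se_k_cat=se_k_cat,
        covariance=np.asarray(pcov), r_squared=max(0.0, min(1.0, r2)),
        converged=converged, warnings=msgs,
    )


def fit_decay(times, residual_fractions) -> DecayFit:
    """First-order inactivation fit A(t) = exp(-k_d t).

    Log-linearized through-origin least squares provides the start value;
    nonlinear refinement on the original scale gives the reported k_d.
    Fractions must lie in (0, 1.05] (zero or negative activities cannot be
    log-transformed and indicate a different decay regime).
    """
    t = np.asarray(times, dtype=float)
    A = np.asarray(residual_fractions, dtype=float)
    require(t.shape == A.shape and t.ndim == 1, "residual_fractions",
            "times and fractions must be equal-length 1-D")
    require(t.size >= 2, "times", "need >= 2 points")
    bad = np.flatnonzero((A <= 0) | (A > 1.05))
    if bad.size:
        rows = ", ".join(f"(t={t[i]:g}, A={A[i]:g})" for i in bad)
        raise ValidationError(
            f"residual_fractions: values outside (0, 1.05] at rows {rows}"
        )

    # through-origin OLS of ln A on t: slope = sum(t lnA)/sum(t^2)
    stt = float((t**2).sum())
    k0 = max(-float((t * np.log(A)).sum()) / stt, 0.0) if stt > 0 else 0.0

    def model(t_, k):
        return np.exp(-k * t_)

    try:
        popt, pcov = curve_fit(
            model, t, A, p0=[max(k0, 1e-12)], xtol=1e-12, ftol=1e-14, maxfev=10000
        )
        k_d = max(float(popt[0]), 0.0)
        se = float(np.sqrt(max(pcov[0, 0], 0.0)))
        if k_d * float(t.max()) < 1e-9:  # indistinguishable from no decay
            k_d, se = 0.0, 0.0
    except (RuntimeError, ValueError):
        k_d, se = k0, float("nan")
    pred = model(t, k_d)
    rss = float(((A - pred) ** 2).sum())
    tss = float(((A - A.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    half_life = math.inf if k_d == 0 else math.log(2.0) / k_d
    return DecayFit(k_d=k_d, half_life=half_life, se_k_d=se,
                    r_squared=max(0.0, min(1.0, r2)))


def profile_summary(x, activity) -> ActivityProfile:
    """Normalize an activity profile to its maximum and locate the optimum.

    x is sorted if needed (with a warning); activities are scaled so the
    maximum is 1.  The optimum is the grid point of maximal activity.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(activity, dtype=float)
    require(x.shape == a.shape and x.ndim == 1, "activity", "x and activity must match")
    require(x.size >= 3, "x", "need >= 3 grid points")
    require(bool(np.all(a >= 0)), "activity", "must be non-negative")
    if np.any(np.diff(x) < 0):
        warnings.warn("x grid was not sorted; sorting", stacklevel=2)
        order = np.argsort(x)
        x, a = x[order], a[order]
    if np.unique(x).size != x.size:
        raise ValidationError("x: duplicate grid points")
    amax = a.max()
    if amax <= 0:
        raise FitError("activity: all zero, profile undefined")
    a = a / amax
    return ActivityProfile(x=x, activity=a, optimum=float(x[int(np.argmax(a))]))


def specific_activity_to_kcat(u_per_mg: float, molar_mass_g_per_mol: float) -> float:
    """Convert a specific activity (U/mg; 1 U = 1 umol/min) to k_cat (1/s).

    k_cat = (umol/min/mg) * (g/mol) / 60 / 1e6 * 1e6 = U/mg * M / 60 / 1000
    with M in g/mol.  Explicit by design: the molar mass must be supplied.
    """
    require(u_per_mg >= 0, "u_per_mg", "must be >= 0")
    require(molar_mass_g_per_mol > 0, "molar_mass_g_per_mol", "must be > 0")
    # U/mg = umol substrate / min / mg enzyme; per mg enzyme there are
    # 1e-3/M mol = 1e3/M umol of enzyme; k_cat = U/mg / (1e3/M) / 60 s
    return u_per_mg * molar_mass_g_per_mol / 1e3 / 60.0
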