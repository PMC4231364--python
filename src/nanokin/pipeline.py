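"""End-to-end workflow: turbidity CSV -> initial rates -> saturation fits.

The interchange dialect is deliberately plain: comma-separated UTF-8 with a
mandatory header row, '.' decimal separator, '#' comment lines, first
column the time axis in minutes, and one turbidity column per assay
condition.  A condition map (YAML) ties each column to its enzyme
concentration (mg/mL or ug/mL, tagged), substrate, temperature and
replicate.  All fits, window and exclusion decisions are logged and written
to a JSON report that reloads losslessly.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FitError, ValidationError, require
from .turbidity import (
    Condition,
    RateDataset,
    SaturationFit,
    TurbidityCurve,
    WindowPolicy,
    fit_saturation,
    fold_change,
    rates_from_curves,
)

logger = logging.getLogger("nanokin")

_UNIT_TO_MG_PER_ML = {"mg/mL": 1.0, "mg/ml": 1.0, "ug/mL": 1e-3, "ug/ml": 1e-3, "µg/mL": 1e-3}


@dataclass(frozen=True)
class ColumnCondition:
    """Condition-map entry for one turbidity column."""

    enzyme_conc: float
    unit: str = "mg/mL"
    substrate: str = "PET"
    temperature: float = 50.0
    replicate: int = 0

    def to_condition(self) -> Condition:
        if self.unit not in _UNIT_TO_MG_PER_ML:
            raise ValidationError(
                f"unit: {self.unit!r} not recognized (use 'mg/mL' or 'ug/mL')"
            )
        require(self.enzyme_conc >= 0, "enzyme_conc", "must be >= 0")
        return Condition(
            enzyme_conc=self.enzyme_conc * _UNIT_TO_MG_PER_ML[self.unit],
            substrate=self.substrate,
            temperature=self.temperature,
            replicate=self.replicate,
        )


@dataclass
class RunConfig:
    """Configuration of one end-to-end turbidimetric analysis run."""

    turbidity_csv: str
    conditions: dict[str, ColumnCondition]  # column name -> condition
    window: WindowPolicy | None = None  # None: per-substrate defaults
    weighted: bool = False
    exclude_supramaximal: bool = True
    fold_change_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    output_dir: str = "nanokin_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        require(len(self.conditions) > 0, "conditions", "must map at least one column")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        try:
            conditions = {
                col: ColumnCondition(**spec) for col, spec in raw["conditions"].items()
            }
        except KeyError as exc:
            raise ValidationError(f"{path}: missing config key {exc}") from exc
        except TypeError as exc:
            raise ValidationError(f"{path}: bad condition entry ({exc})") from exc
        window = None
        if raw.get("window"):
            window = WindowPolicy(**raw["window"])
        return cls(
            turbidity_csv=raw.get("turbidity_csv", ""),
            conditions=conditions,
            window=window,
            weighted=bool(raw.get("weighted", False)),
            exclude_supramaximal=bool(raw.get("exclude_supramaximal", True)),
            fold_change_pairs=[tuple(p) for p in raw.get("fold_change_pairs", [])],
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "nanokin_out")),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def canonical_dict(self) -> dict:
        return {
            "turbidity_csv": self.turbidity_csv,
            "conditions": {
                col: vars(c).copy() for col, c in sorted(self.conditions.items())
            },
            "window": None if self.window is None else vars(self.window).copy(),
            "weighted": self.weighted,
            "exclude_supramaximal": self.exclude_supramaximal,
            "fold_change_pairs": [list(p) for p in self.fold_change_pairs],
            "seed": self.seed,
        }

    def digest(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_turbidity_csv(path: str | Path, config: RunConfig) -> list[TurbidityCurve]:
    """Read a turbidity CSV into curves using the config's condition map.

    The first column is the time axis (minutes).  Mapped columns become
    curves; unmapped columns are skipped with a warning; blank or
    non-numeric cells raise an error naming the cell.
    """
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except (OSError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: cannot read CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a time column plus >= 1 turbidity column")
    time_col = df.columns[0]

    def _numeric(col: str) -> np.ndarray:
        series = pd.to_numeric(df[col].str.strip() if df[col].dtype == object else df[col],
                               errors="coerce")
        bad = series.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raw = df[col].iloc[row]
            what = "blank cell" if (pd.isna(raw) or str(raw).strip() == "") else f"non-numeric value {raw!r}"
            raise ValidationError(
                f"{path}: {what} in column {col!r}, data row {row + 1}"
            )
        return series.to_numpy(dtype=float)

    times = _numeric(time_col)
    missing = [c for c in config.conditions if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: mapped columns not found: {missing}")
    curves = []
    for col in df.columns[1:]:
        if col not in config.conditions:
            logger.warning("column %r has no condition mapping; skipped", col)
            continue
        curves.append(
            TurbidityCurve(
                times=times,
                turbidity=_numeric(col),
                condition=config.conditions[col].to_condition(),
            )
        )
    if not curves:
        raise ValidationError(f"{path}: no mapped turbidity columns")
    return curves


def write_turbidity_csv(
    curves: Sequence[TurbidityCurve], path: str | Path, seed: int | None = None
) -> dict[str, ColumnCondition]:
    """Write curves as a single CSV (shared time axis) + return the condition
    map.  The RNG seed, when given, is recorded in a header comment."""
    require(len(curves) > 0, "curves", "must not be empty")
    times = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, times):
            raise ValidationError("curves: all curves must share one time axis")
    cols, condmap = {}, {}
    for c in curves:
        label = (
            f"{c.condition.substrate}_T{c.condition.temperature:g}"
            f"_E{c.condition.enzyme_conc:g}_r{c.condition.replicate}"
        )
        cols[label] = c.turbidity
        condmap[label] = ColumnCondition(
            enzyme_conc=c.condition.enzyme_conc,
            unit="mg/mL",
            substrate=c.condition.substrate,
            temperature=c.condition.temperature,
            replicate=c.condition.replicate,
        )
    df = pd.DataFrame({"time_min": times, **cols})
    header = "# nanokin turbidity traces\n"
    if seed is not None:
        header += f"# seed={seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return condmap


def write_condition_map(condmap: dict[str, ColumnCondition], path: str | Path) -> None:
    payload = {"conditions": {col: vars(c).copy() for col, c in condmap.items()}}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class ConditionResult:
    """Outcome for one substrate/temperature condition."""

    key: str
    status: str  # "ok" | "failed"
    fit: SaturationFit | None
    rates: RateDataset | None
    error: str = ""


@dataclass
class FitReport:
    """Serializable record of a full pipeline run."""

    version: str
    seed: int
    config_hash: str
    conditions: dict[str, ConditionResult]
    fold_changes: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        out = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "conditions": {},
            "fold_changes": self.fold_changes,
        }
        for key, res in sorted(self.conditions.items()):
            entry: dict = {"status": res.status}
            if res.fit is not None:
                entry["fit"] = res.fit.to_dict()
            if res.rates is not None:
                entry["rates"] = [
                    {
                        "enzyme_conc_mg_per_mL": p.enzyme_conc,
                        "rate_per_min": p.rate,
                        "rate_se": p.rate_se,
                        "n_replicates": p.n_replicates,
                    }
                    for p in res.rates.points
                ]
            if res.error:
                entry["error"] = res.error
            out["conditions"][key] = entry
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def run_pipeline(config: RunConfig) -> FitReport:
    """Execute read -> rates -> saturation fit -> fold changes.

    Conditions (substrate/temperature groups) are processed independently:
    a failure in one is recorded in its report entry and does not affect
    the others.  Deterministic for fixed inputs and seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    curves = read_turbidity_csv(config.turbidity_csv, config)

    groups: dict[str, list[TurbidityCurve]] = {}
    for c in curves:
        groups.setdefault(c.condition.key, []).append(c)

    results: dict[str, ConditionResult] = {}
    for key in sorted(groups):
        group = groups[key]
        try:
            window = config.window or WindowPolicy.for_substrate(
                group[0].condition.substrate
            )
            rates = rates_from_curves(group, window)
            logger.info("[%s] window policy: %s", key, window)
            fit = fit_saturation(
                rates,
                weighted=config.weighted,
                exclude_supramaximal=config.exclude_supramaximal,
            )
            for p in fit.excluded_points:
                logger.info(
                    "[%s] excluded supra-maximal point E=%g mg/mL (rate %g)",
                    key, p.enzyme_conc, p.rate,
                )
            if not fit.converged:
                raise FitError(f"saturation fit did not converge: {fit.message}")
            results[key] = ConditionResult(key, "ok", fit, rates)
        except (ValidationError, FitError) as exc:
            logger.error("[%s] stage failed: %s", key, exc)
            results[key] = ConditionResult(key, "failed", None, None, error=str(exc))

    fold_changes: dict[str, dict[str, float]] = {}
    for a, b in config.fold_change_pairs:
        label = f"{b}/{a}"
        ra, rb = results.get(a), results.get(b)
        if ra is None or rb is None or ra.fit is None or rb.fit is None:
            raise ValidationError(f"fold_change_pairs: missing fitted condition in ({a}, {b})")
        fc = fold_change(ra.fit, rb.fit)
        fold_changes[label] = {
            "k_tau_ratio": fc.k_tau_ratio,
            "k_tau_ratio_2sf": fc.k_tau_ratio_2sf,
            "K_A_ratio": fc.K_A_ratio,
            "K_A_ratio_2sf": fc.K_A_ratio_2sf,
        }

    report = FitReport(
        version=__version__,
        seed=config.seed,
        config_hash=config.digest(),
        conditions=results,
        fold_changes=fold_changes,
    )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    rows = []
    for key, res in sorted(results.items()):
        if res.rates is None:
            continue
        for p in res.rates.points:
            rows.append(
                {
                    "condition": key,
                    "enzyme_conc_mg_per_mL": p.enzyme_conc,
                    "rate_per_min": p.rate,
                    "rate_se": p.rate_se,
                    "n_replicates": p.n_replicates,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "rates.csv", index=False)
    return report


def fold_change_report(
    report: FitReport, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Ratio table (full precision and 2 s.f.) for condition pairs (a, b)."""
    rows = []
    for a, b in pairs:
        ra, rb = report.conditions.get(a), report.conditions.get(b)
        if ra is None or ra.fit is None:
            raise ValidationError(f"pairs: condition {a!r} missing or unfitted")
        if rb is None or rb.fit is None:
            raise ValidationError(f"pairs: condition {b!r} missing or unfitted")
        fc = fold_change(ra.fit, rb.fit)
        rows.append(
            {
                "pair": f"{b}/{a}",
                "k_tau_ratio": fc.k_tau_ratio,
                "k_tau_ratio_2sf": fc.k_tau_ratio_2sf,
                "K_A_ratio": fc.K_A_ratio,
                "K_A_ratio_2sf": fc.K_A_ratio_2sf,
            }
        )
    return pd.DataFrame(rows)
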