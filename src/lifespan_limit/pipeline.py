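"""Per-year analysis orchestration and multi-year aggregation.

For each calendar year the pipeline runs

    life table -> survival curve -> characteristic age alpha
               -> pointwise exponent beta(x) -> quadratic fit over the
                  extreme-age window -> omega from beta(x) = gamma(x)

and the per-year maximum mathematical lifespans are summarised as
mean +/- SD over the year range (years with no finite omega are excluded
and counted, never imputed at the search bound).  ``run_analysis`` wraps
this for a whole HMD file, writing a JSON report and a per-year CSV.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lifetable_io import (
    LifeTable,
    LifeTableError,
    YearNotFoundError,
    available_years,
    read_hmd_lifetable,
    survival_from_lifetable,
)
from .model import (
    ModelError,
    OmegaEstimate,
    StretchedExpFit,
    estimate_alpha,
    extract_beta,
    fit_beta_quadratic,
    solve_omega,
)

__all__ = [
    "AnalysisConfig",
    "load_config",
    "YearResult",
    "OmegaSummary",
    "PipelineError",
    "AggregationError",
    "analyze_year",
    "aggregate_omegas",
    "run_analysis",
]

logger = logging.getLogger("lifespan_limit")

CSV_COLUMNS = ["year", "alpha", "b0", "b1", "b2", "residual_rms", "omega", "status"]


class PipelineError(RuntimeError):
    """A stage failure annotated with the year and stage it occurred in."""

    def __init__(self, year: int, stage: str, message: str):
        self.year = year
        self.stage = stage
        super().__init__(f"year {year}, stage {stage}: {message}")


class AggregationError(ValueError):
    """No finite omega available to aggregate."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable pipeline settings.

    fit_window : half-open age window [x_lo, x_hi) for the quadratic
        exponent fit (years); the default 100–110 covers "extreme ages"
        while excluding the 110+ open-interval row.
    search_bound : upper age limit of the omega root search (years).
    grid_step : bracketing grid step of the root search (years).
    solver_tolerance : bisection tolerance on omega (years).
    sd_convention : 'population' (divisor n) or 'sample' (n - 1) for the
        across-year SD; both are always reported.
    dialect : input dialect, 'auto' selects by file extension.
    """

    fit_window: tuple[float, float] = (100.0, 110.0)
    search_bound: float = 200.0
    grid_step: float = 0.1
    solver_tolerance: float = 1e-6
    sd_convention: str = "population"
    dialect: str = "auto"

    def __post_init__(self) -> None:
        if self.sd_convention not in ("population", "sample"):
            raise ValueError(
                f"sd_convention must be 'population' or 'sample', got {self.sd_convention!r}"
            )


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a flat JSON or key=value file."""
    text = Path(path).read_text(encoding="utf-8").strip()
    if text.startswith("{"):
        raw = json.loads(text)
    else:
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    kwargs: dict = {}
    for key in ("fit_window",):
        if key in raw:
            v = raw[key]
            if isinstance(v, str):
                v = [float(t) for t in v.replace(":", ",").split(",")]
            kwargs[key] = (float(v[0]), float(v[1]))
    for key in ("search_bound", "grid_step", "solver_tolerance"):
        if key in raw:
            kwargs[key] = float(raw[key])
    for key in ("sd_convention", "dialect"):
        if key in raw:
            kwargs[key] = str(raw[key])
    return AnalysisConfig(**kwargs)


@dataclass
class YearResult:
    """Everything the pipeline learned about one population-year."""

    year: int
    status: str  # 'ok' | 'no_finite_omega' | 'error'
    alpha: float = math.nan
    fit: StretchedExpFit | None = None
    omega_estimate: OmegaEstimate | None = None
    message: str = ""

    @property
    def omega(self) -> float:
        if self.omega_estimate is None:
            return math.nan
        return self.omega_estimate.omega


@dataclass
class OmegaSummary:
    """Across-year summary: omega = mean +/- SD over the usable years."""

    population_label: str
    years: list[int]
    omegas: list[float]  # aligned with years; NaN where no finite root
    mean_omega: float
    sd_omega: float
    sd_population: float
    sd_sample: float
    sd_convention: str
    n_years_used: int


def analyze_year(table: LifeTable, config: AnalysisConfig | None = None) -> YearResult:
    """Run the full single-year chain on one life table.

    Stage errors (no 1/e crossing, too few extreme-age points, ...) are
    re-raised as PipelineError annotated with year and stage.  A model with
    no finite omega below the search bound is a normal outcome
    (status='no_finite_omega'), not an exception.
    """
    config = config or AnalysisConfig()
    year = table.year

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except (ModelError, LifeTableError) as exc:
            raise PipelineError(year, name, str(exc)) from exc
        logger.info("year %d: %s done", year, name)
        return result

    curve = stage("survival_from_lifetable", survival_from_lifetable, table)
    alpha = stage("estimate_alpha", estimate_alpha, curve)
    profile = stage("extract_beta", extract_beta, curve, alpha)
    fit = stage("fit_beta_quadratic", fit_beta_quadratic, profile, config.fit_window)
    omega_est = stage(
        "solve_omega",
        solve_omega,
        fit,
        config.search_bound,
        config.grid_step,
        config.solver_tolerance,
    )
    status = "ok" if omega_est.is_finite else "no_finite_omega"
    return YearResult(
        year=year, status=status, alpha=alpha, fit=fit, omega_estimate=omega_est
    )


def aggregate_omegas(
    omegas_by_year: Mapping[int, float] | Sequence[YearResult],
    population_label: str = "",
    sd_convention: str = "population",
) -> OmegaSummary:
    """Mean and SD of the finite per-year omega values.

    Accepts either ``{year: omega}`` (NaN for no finite root) or a sequence
    of YearResult.  Years without a finite omega are excluded from the mean
    and SD and from ``n_years_used``.
    """
    if not isinstance(omegas_by_year, Mapping):
        omegas_by_year = {r.year: r.omega for r in omegas_by_year}
    years = sorted(omegas_by_year)
    omegas = [float(omegas_by_year[y]) for y in years]
    finite = np.array([w for w in omegas if math.isfinite(w)])
    if finite.size == 0:
        raise AggregationError("no estimable limit: no year produced a finite omega")
    sd_pop = float(np.std(finite, ddof=0))
    sd_samp = float(np.std(finite, ddof=1)) if finite.size > 1 else math.nan
    return OmegaSummary(
        population_label=population_label,
        years=years,
        omegas=omegas,
        mean_omega=float(np.mean(finite)),
        sd_omega=sd_pop if sd_convention == "population" else sd_samp,
        sd_population=sd_pop,
        sd_sample=sd_samp,
        sd_convention=sd_convention,
        n_years_used=int(finite.size),
    )


def _result_record(res: YearResult) -> dict:
    rec = {
        "year": res.year,
        "status": res.status,
        "alpha": res.alpha,
        "omega": res.omega,
        "message": res.message,
    }
    if res.fit is not None:
        rec.update(
            b0=res.fit.b0,
            b1=res.fit.b1,
            b2=res.fit.b2,
            fit_window=list(res.fit.fit_window),
            n_points=res.fit.n_points,
            residual_rms=res.fit.residual_rms,
        )
    if res.omega_estimate is not None:
        rec.update(
            bracket=list(res.omega_estimate.bracket)
            if res.omega_estimate.bracket
            else None,
            search_bound=res.omega_estimate.search_bound,
            solver_tolerance=res.omega_estimate.solver_tolerance,
        )
    return rec


def _jsonify(obj):
    """Strict-JSON sanitizer: non-finite floats become null."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def run_analysis(
    input_path: str | Path,
    population_label: str,
    year_range: tuple[int, int] | Iterable[int] | None = None,
    config: AnalysisConfig | None = None,
    out_json: str | Path | None = None,
    out_csv: str | Path | None = None,
) -> dict:
    """Analyse a whole life-table file over a year range and report.

    Years absent from the file, or failing a stage, are logged and skipped;
    the summary covers the years that produced a finite omega.  Returns the
    report dict (also written to ``out_json``/``out_csv`` when given).

    Raises AggregationError if no year at all yields a finite omega.
    """
    config = config or AnalysisConfig()
    if year_range is None:
        years = available_years(input_path)
    elif isinstance(year_range, tuple) and len(year_range) == 2:
        years = list(range(year_range[0], year_range[1] + 1))
    else:
        years = list(year_range)

    results: list[YearResult] = []
    for year in years:
        try:
            table = read_hmd_lifetable(input_path, year)
        except YearNotFoundError as exc:
            logger.warning("skipping year %d: %s", year, exc)
            results.append(YearResult(year=year, status="error", message=str(exc)))
            continue
        try:
            results.append(analyze_year(table, config))
        except PipelineError as exc:
            logger.warning("%s", exc)
            results.append(YearResult(year=year, status="error", message=str(exc)))

    usable = {r.year: r.omega for r in results if r.status in ("ok", "no_finite_omega")}
    summary = aggregate_omegas(usable, population_label, config.sd_convention)

    report = {
        "population": population_label,
        "input": str(input_path),
        "config": asdict(config),
        "per_year": [_result_record(r) for r in results],
        "summary": {
            "years": summary.years,
            "omegas": summary.omegas,
            "mean_omega": summary.mean_omega,
            "sd_omega": summary.sd_omega,
            "sd_population": summary.sd_population,
            "sd_sample": summary.sd_sample,
            "sd_convention": summary.sd_convention,
            "n_years_used": summary.n_years_used,
            "n_years_failed": sum(1 for r in results if r.status == "error"),
        },
    }
    if out_json is not None:
        Path(out_json).write_text(
            json.dumps(_jsonify(report), indent=2), encoding="utf-8"
        )
        logger.info("wrote JSON report to %s", out_json)
    if out_csv is not None:
        rows = [
            {
                "year": r.year,
                "alpha": r.alpha,
                "b0": r.fit.b0 if r.fit else math.nan,
                "b1": r.fit.b1 if r.fit else math.nan,
                "b2": r.fit.b2 if r.fit else math.nan,
                "residual_rms": r.fit.residual_rms if r.fit else math.nan,
                "omega": r.omega,
                "status": r.status,
            }
            for r in results
        ]
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(out_csv, index=False)
        logger.info("wrote per-year CSV to %s", out_csv)
    return report
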