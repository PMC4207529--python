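"""File formats: series CSV, parameter files, and result writers.

Series travel as two-column CSV with header ``year,value`` (UTF-8, ``.``
decimal separator).  All numeric output is written with 12 significant
digits so round-trips through text are lossless at double precision for
practical purposes.  Writers are atomic: content goes to a temporary file
in the destination directory and is renamed into place.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ar import ARModel, OrderSelection
from .diagnostics import ControlChartResult, CorrelogramResult
from .eil import YearlySeries
from .errors import SeriesFormatError
from .forecast import Backtest, Forecast

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_parameters",
    "write_model_report",
    "write_comparison_table",
    "write_chart_summary",
    "write_correlogram_csv",
    "write_forecast_csv",
    "write_backtest_csv",
]

FLOAT_FMT = "%.12g"


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(x: float) -> str:
    return FLOAT_FMT % float(x)


def read_series_csv(path: str | Path) -> YearlySeries:
    """Read a ``year,value`` CSV into a :class:`YearlySeries`.

    Raises :class:`SeriesFormatError` naming the offending line for a bad
    header, non-numeric fields, or non-consecutive years.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise SeriesFormatError(f"{path}: empty file")
    header = [c.strip().lower() for c in lines[0].split(",")]
    if header != ["year", "value"]:
        raise SeriesFormatError(f"{path}:1: expected header 'year,value', got {lines[0]!r}")
    years, values = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [c.strip() for c in line.split(",")]
        if len(parts) != 2:
            raise SeriesFormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        try:
            years.append(int(parts[0]))
        except ValueError as err:
            raise SeriesFormatError(f"{path}:{lineno}: year {parts[0]!r} is not an integer") from err
        try:
            values.append(float(parts[1]))
        except ValueError as err:
            raise SeriesFormatError(f"{path}:{lineno}: value {parts[1]!r} is not numeric") from err
    try:
        return YearlySeries(years=np.array(years), values=np.array(values))
    except ValueError as err:
        raise SeriesFormatError(f"{path}: {err}") from err


def write_series_csv(series: YearlySeries, path: str | Path) -> None:
    lines = ["year,value"]
    lines += [f"{int(y)},{_fmt(v)}" for y, v in zip(series.years, series.values)]
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_parameters(path: str | Path) -> dict[str, float]:
    """Read EIL parameters from YAML or flat ``key=value`` text.

    Recognized keys: C, V, I, D, K (V optional when prices come from a
    series file); unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    content = [ln for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")]
    if content and "=" in content[0]:
        data = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SeriesFormatError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, val = line.partition("=")
            data[key.strip()] = val.strip()
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SeriesFormatError(f"{path}: expected a mapping of EIL parameters")
    allowed = {"C", "V", "I", "D", "K"}
    unknown = set(data) - allowed
    if unknown:
        raise SeriesFormatError(f"{path}: unknown parameter key(s) {sorted(unknown)}")
    try:
        return {k: float(v) for k, v in data.items()}
    except (TypeError, ValueError) as err:
        raise SeriesFormatError(f"{path}: non-numeric parameter value: {err}") from err


def write_model_report(model: ARModel, path: str | Path) -> None:
    """Flat key/value JSON report of a fitted AR model."""
    report = {
        "p": model.p,
        **{f"a_{j + 1}": model.coeffs[j] for j in range(model.p)},
        "intercept": model.intercept,
        "mean": model.mean,
        "sigma2": model.sigma2,
        "loglik": model.loglik,
        "loglik_kind": model.loglik_kind,
        "n_params": model.n_params,
        "aic": model.aic,
    }
    text = json.dumps({k: (v if isinstance(v, (int, str)) else float(_fmt(v)))
                       for k, v in report.items()}, indent=2)
    _atomic_write_text(path, text + "\n")


def write_comparison_table(selection: OrderSelection, path: str | Path) -> None:
    """Order-comparison table CSV: order, a_1.., intercept, sigma2, loglik, aic."""
    df: pd.DataFrame = selection.table
    _atomic_write_text(path, df.to_csv(index=False, float_format=FLOAT_FMT))


def write_chart_summary(
    chart: ControlChartResult, series: YearlySeries, path: str | Path
) -> None:
    outlier_years = ";".join(str(int(series.years[i])) for i in chart.outliers)
    lines = [
        "statistic,value",
        f"center,{_fmt(chart.center)}",
        f"sigma_hat,{_fmt(chart.sigma_hat)}",
        f"ucl,{_fmt(chart.ucl)}",
        f"lcl,{_fmt(chart.lcl)}",
        f"mr_center,{_fmt(chart.mr_center)}",
        f"mr_ucl,{_fmt(chart.mr_ucl)}",
        f"multiplier,{_fmt(chart.multiplier)}",
        f"degenerate,{int(chart.degenerate)}",
        f"outlier_years,{outlier_years}",
    ]
    _atomic_write_text(path, "\n".join(lines) + "\n")


def write_correlogram_csv(corr: CorrelogramResult, path: str | Path) -> None:
    lines = ["lag,acf,pacf,ci_halfwidth"]
    for lag, r, pr, ci in zip(corr.lags, corr.acf, corr.pacf, corr.ci_halfwidth):
        lines.append(f"{int(lag)},{_fmt(r)},{_fmt(pr)},{_fmt(ci)}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def write_forecast_csv(fc: Forecast, path: str | Path) -> None:
    lines = ["year,point,lower,upper,forecast_sd"]
    for y, pt, lo, hi, sd in zip(fc.years, fc.point, fc.pi_lower, fc.pi_upper, fc.forecast_sd):
        lines.append(f"{int(y)},{_fmt(pt)},{_fmt(lo)},{_fmt(hi)},{_fmt(sd)}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def write_backtest_csv(bt: Backtest, path: str | Path) -> None:
    lines = ["year,observed,predicted"]
    for y, obs, pred in zip(bt.years, bt.observed, bt.predicted):
        lines.append(f"{int(y)},{_fmt(obs)},{_fmt(pred)}")
    _atomic_write_text(path, "\n".join(lines) + "\n")
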