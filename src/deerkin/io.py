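"""File formats, run configuration and result serialisation.

All on-disk formats are delimited text (comma or tab, autodetected on
read, comma on write) with unit-bearing column headers:

* DEER traces:            ``t_us,signal``
* stopped-flow traces:    ``t_s,signal``
* product time courses:   ``t_s,product_pct``
* MST titrations:         ``conc_uM,signal``

Numbers are written with 9 significant digits.  Fit outputs are JSON
documents validated by the pydantic models below; their JSON schema is
available from :func:`fit_output_schema`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import InvalidInputError, ParseError
from .forward import DeerTrace
from .inverse import FitResult
from .kinetics import FretTrace

__all__ = [
    "read_trace",
    "read_deer_trace",
    "read_fret_trace",
    "read_xy",
    "write_deer_trace",
    "write_fret_trace",
    "write_xy",
    "RunConfig",
    "DeerFitOutput",
    "fit_result_to_output",
    "fit_output_schema",
    "sig9",
]

_HEADERS = {
    "deer": ("t_us", "signal"),
    "fret": ("t_s", "signal"),
    "product": ("t_s", "product_pct"),
    "mst": ("conc_uM", "signal"),
}


def sig9(x: float) -> float:
    """Round to 9 significant digits (serialisation precision)."""
    return float(f"{float(x):.9g}")


def _read_two_columns(path, kind: str) -> pd.DataFrame:
    cols = _HEADERS[kind]
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except (pd.errors.ParserError, ValueError, csv.Error) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if tuple(df.columns[:2]) != cols:
        raise ParseError(
            f"{path}: expected header {','.join(cols)!r}, got "
            f"{','.join(map(str, df.columns[:2]))!r}"
        )
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    for col in cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            line = int(np.argmax((df[col].isna() | bad).to_numpy())) + 2
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    return df


def read_deer_trace(path) -> DeerTrace:
    """Read a DEER trace; the time axis is shifted so it starts at zero
    (initial-delay correction) if needed."""
    df = _read_two_columns(path, "deer")
    t = df["t_us"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0)) + 2
        raise InvalidInputError(f"{path}: non-increasing time axis near line {i}")
    return DeerTrace(t_us=t - t[0], signal=df["signal"].to_numpy(dtype=float))


def read_fret_trace(path, e0: float, s0: float) -> FretTrace:
    df = _read_two_columns(path, "fret")
    t = df["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0)) + 2
        raise InvalidInputError(f"{path}: non-increasing time axis near line {i}")
    return FretTrace(time_s=t, signal=df["signal"].to_numpy(dtype=float),
                     e0=e0, s0=s0)


def read_xy(path, kind: str):
    """Read a two-column file of the given kind; returns (x, y) arrays."""
    if kind not in _HEADERS:
        raise InvalidInputError(f"unknown trace kind {kind!r}")
    df = _read_two_columns(path, kind)
    x = df[_HEADERS[kind][0]].to_numpy(dtype=float)
    if kind in ("fret", "product", "deer") and np.any(np.diff(x) <= 0):
        i = int(np.argmax(np.diff(x) <= 0)) + 2
        raise InvalidInputError(f"{path}: non-increasing time axis near line {i}")
    return x, df[_HEADERS[kind][1]].to_numpy(dtype=float)


def read_trace(path, kind: str):
    """Typed reader dispatch: ``deer`` gives a DeerTrace, other kinds give
    (x, y) arrays."""
    if kind == "deer":
        return read_deer_trace(path)
    return read_xy(path, kind)


def _write_two_columns(path, kind: str, x, y) -> None:
    cols = _HEADERS[kind]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for xi, yi in zip(np.asarray(x), np.asarray(y)):
            fh.write(f"{xi:.9g},{yi:.9g}\n")


def write_deer_trace(path, trace: DeerTrace) -> None:
    _write_two_columns(path, "deer", trace.t_us, trace.signal)


def write_fret_trace(path, trace: FretTrace) -> None:
    _write_two_columns(path, "fret", trace.time_s, trace.signal)


def write_xy(path, kind: str, x, y) -> None:
    if kind not in _HEADERS:
        raise InvalidInputError(f"unknown trace kind {kind!r}")
    _write_two_columns(path, kind, x, y)


# ---------------------------------------------------------------------------
# Run configuration and fit-output documents
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Configuration of one pipeline run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    scenario: str
    out_dir: str = "."
    seed: int = 0
    snr: float = 100.0
    n_iter: int = 200_000
    n_components: int = 3
    noise_sigma: float = 0.01


class GaussianComponentOutput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fraction: float
    r_nm: float
    dr_nm: float
    artifact: bool = False


class DeerFitOutput(BaseModel):
    """Serialised multi-Gaussian DEER fit (mirrors FitResult)."""

    model_config = ConfigDict(extra="forbid")

    components: list[GaussianComponentOutput]
    chi2: float
    converged: bool
    seed: int
    n_iter: int
    xi_best: float | None = None
    alpha_best: float | None = None
    lambda_: float | None = Field(default=None, alias="lambda")
    dr_uncertainty_nm: list[float] | None = None


def fit_result_to_output(fit: FitResult) -> DeerFitOutput:
    flags = fit.artifact_flags or (False,) * len(fit.distribution.components)
    comps = [
        GaussianComponentOutput(
            fraction=sig9(c.fraction),
            r_nm=sig9(c.r_mean),
            dr_nm=sig9(c.r_sd),
            artifact=bool(flag),
        )
        for c, flag in zip(fit.distribution.components, flags)
    ]
    return DeerFitOutput(
        components=comps,
        chi2=sig9(fit.chi2),
        converged=fit.converged,
        seed=fit.seed,
        n_iter=fit.n_iter,
        xi_best=None if fit.xi_best is None else sig9(fit.xi_best),
        alpha_best=None if fit.alpha_best is None else sig9(fit.alpha_best),
        **{"lambda": None if fit.lam_best is None else sig9(fit.lam_best)},
        dr_uncertainty_nm=(
            None
            if fit.r_sd_uncertainty is None
            else [sig9(u) for u in fit.r_sd_uncertainty]
        ),
    )


def fit_output_schema() -> dict:
    """JSON schema of the DEER fit output document."""
    return DeerFitOutput.model_json_schema(by_alias=True)


def write_json(path, payload) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(payload, BaseModel):
        path.write_text(payload.model_dump_json(indent=2, by_alias=True) + "\n")
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")
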