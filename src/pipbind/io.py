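"""CSV/JSON I/O and run configuration.

CSV is the single tabular interchange format: one series per file with
columns ``conc``, optional ``conc_unit`` and replicate columns
``rep1..repN``.  Calibration constants travel in a JSON sidecar
({"r_free": ..., "r_bound": ..., "q_ratio": ...}).  Structured results are
written as JSON with stable key order, embedding the package version and
the configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .assay import AnisotropyCalibration, CompetitionSeries, TitrationSeries
from .errors import ParseError, SeriesValidationError

__all__ = [
    "UNIT_FACTORS",
    "RunConfig",
    "read_series_csv",
    "read_calibration_json",
    "write_series_csv",
    "write_result_json",
]

UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class RunConfig:
    """Validated options shared by CLI commands and result files."""

    unit: str = "M"
    qc_alpha: float = 0.05
    model: str = "auto"  # auto | complete | incomplete
    selection_threshold: float = 0.05
    n_starts: int = 3
    seed: int = 0
    motif_preset: str = "strict"
    orientation: str = "both"
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    anchor_threshold: float = 70.0

    def __post_init__(self) -> None:
        if self.unit not in UNIT_FACTORS:
            raise SeriesValidationError(
                f"unknown unit {self.unit!r}; expected one of {sorted(UNIT_FACTORS)}"
            )
        if not 0 < self.qc_alpha < 1:
            raise SeriesValidationError("qc_alpha must be in (0, 1)")
        if self.model not in ("auto", "complete", "incomplete"):
            raise SeriesValidationError(f"unknown model {self.model!r}")
        if self.motif_preset not in ("strict", "relaxed"):
            raise SeriesValidationError(f"unknown motif preset {self.motif_preset!r}")
        if self.orientation not in ("forward", "reverse", "both"):
            raise SeriesValidationError(f"unknown orientation {self.orientation!r}")
        if self.n_starts < 1 or self.sasa_n_points < 10:
            raise SeriesValidationError("n_starts >= 1 and sasa_n_points >= 10 required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _points_from_frame(df: pd.DataFrame, path, unit: Optional[str]):
    cols = {c.strip(): c for c in df.columns}
    if "conc" not in cols:
        raise ParseError(f"{path}: missing required column 'conc'")
    rep_cols = sorted(
        (c for c in df.columns if c.strip().lower().startswith("rep")),
        key=lambda c: int("".join(filter(str.isdigit, c)) or 0),
    )
    if not rep_cols:
        raise ParseError(f"{path}: no replicate columns (rep1..repN) found")
    if unit is None:
        if "conc_unit" in cols:
            units = df[cols["conc_unit"]].astype(str).unique()
            if len(units) != 1:
                raise ParseError(f"{path}: mixed conc_unit values {list(units)}")
            unit = units[0]
        else:
            unit = "M"
    if unit not in UNIT_FACTORS:
        raise ParseError(f"{path}: unknown concentration unit {unit!r}")
    factor = UNIT_FACTORS[unit]
    try:
        conc = df[cols["conc"]].astype(float).to_numpy() * factor
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value in 'conc': {exc}") from exc
    points = []
    for i, c in enumerate(conc):
        reps = []
        for rc in rep_cols:
            v = df[rc].iloc[i]
            if pd.isna(v):
                continue
            try:
                reps.append(float(v))
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: row {i + 1}: non-numeric replicate in {rc!r}"
                ) from exc
        if not reps:
            raise ParseError(f"{path}: row {i + 1}: no replicate values")
        points.append((float(c), tuple(reps)))
    points.sort(key=lambda p: p[0])
    concs = [p[0] for p in points]
    if len(set(concs)) != len(concs):
        raise ParseError(f"{path}: duplicate concentrations after unit conversion")
    return tuple(points)


def read_series_csv(
    path,
    kind: str = "titration",
    unit: Optional[str] = None,
    probe_total: float = 50e-9,
    protein_total: float = 1e-6,
    calibration: Optional[AnisotropyCalibration] = None,
):
    """Read a titration or competition series from CSV.

    Rows may appear in any order; the series is sorted by concentration.
    ``unit`` overrides any ``conc_unit`` column; default is molar.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read CSV {path}: {exc}") from exc
    points = _points_from_frame(df, path, unit)
    if kind == "titration":
        return TitrationSeries(probe_total=probe_total, points=points)
    if kind == "competition":
        cal = calibration or AnisotropyCalibration(0.0470, 0.1587, 0.70)
        return CompetitionSeries(
            probe_total=probe_total, protein_total=protein_total,
            points=points, calibration=cal,
        )
    raise SeriesValidationError(f"unknown series kind {kind!r}")


def read_calibration_json(path) -> AnisotropyCalibration:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot read calibration {path}: {exc}") from exc
    try:
        return AnisotropyCalibration(
            r_free=float(data["r_free"]),
            r_bound=float(data["r_bound"]),
            q_ratio=float(data.get("q_ratio", 1.0)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing calibration key {exc}") from exc


def write_series_csv(series, path, unit: str = "M") -> None:
    """Write a series in the same CSV layout :func:`read_series_csv` reads."""
    factor = UNIT_FACTORS[unit]
    n_rep = max(len(reps) for _, reps in series.points)
    rows = []
    for conc, reps in series.points:
        row = {"conc": conc / factor, "conc_unit": unit}
        for j in range(n_rep):
            row[f"rep{j + 1}"] = reps[j] if j < len(reps) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    return obj


def write_result_json(result, path, config: Optional[RunConfig] = None, seed: Optional[int] = None) -> None:
    """Serialize a result object to JSON with stable key order.

    NaN standard errors become null; the package version, configuration
    and seed are embedded so a result file is self-describing.  Reading
    the file back yields the identical payload (lossless round-trip)."""
    payload = {
        "package": "pipbind",
        "version": __version__,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "result": _jsonable(result),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
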