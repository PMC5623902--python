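"""File I/O, run configuration, and the published-panel regression check.

CSV schemas (long format, header required, UTF-8, decimal point):

* checkerboard: ``dose_a_nM, dose_b_nM, replicate, viability`` (or
  ``signal`` for raw readings, normalized on read); optional
  ``dose_unit`` column overrides the nM default;
* single-agent series: ``drug, dose_nM, replicate, signal|viability``;
* synergy report: JSON (full, with a ``raw`` sub-object at full
  precision) or a one-row CSV shaped like the published panel table.

Numbers in reports are serialized to 4 significant digits; not-available
values render as ``NA``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .dose_response import DoseSeries, normalize_viability
from .response_surface import Checkerboard
from .synergy_metrics import LABEL_ALIASES, SynergyReport, classify

logger = logging.getLogger("combosurf")

__all__ = [
    "RunConfig",
    "read_checkerboard_csv",
    "write_checkerboard_csv",
    "read_dose_series_csv",
    "write_report",
    "read_report",
    "load_table1",
    "run_table1_check",
]

_UNIT_TO_NM = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


@dataclass
class RunConfig:
    """Thresholds, fit settings, and ray construction for one analysis run.

    Defaults are the published classification thresholds (CI 0.7/1.3,
    blending +/-20) and the package's standard fit profile.
    """

    ci_synergy: float = 0.7
    ci_subadditive: float = 1.3
    blending_synergy: float = 20.0
    blending_subadditive: float = -20.0
    hill_restarts: int = 16
    surface_restarts: int = 4
    seed: int = 0
    isobole_points: int = 201
    blending_total: float = 1.0
    blending_fractions: int = 101
    log_level: str = "WARNING"
    input_path: str = ""
    output_path: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_synergy < self.ci_subadditive):
            raise ValueError("require ci_synergy < ci_subadditive")
        if not (self.blending_subadditive < self.blending_synergy):
            raise ValueError("require blending_subadditive < blending_synergy")
        for name in ("ci_synergy", "ci_subadditive", "blending_synergy",
                     "blending_subadditive"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")

    @property
    def thresholds(self) -> dict:
        return {
            "ci_synergy": self.ci_synergy,
            "ci_subadditive": self.ci_subadditive,
            "blending_synergy": self.blending_synergy,
            "blending_subadditive": self.blending_subadditive,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _dose_scale(df: pd.DataFrame) -> np.ndarray:
    if "dose_unit" not in df.columns:
        return np.ones(len(df))
    scale = df["dose_unit"].map(_UNIT_TO_NM)
    if scale.isna().any():
        bad = df.loc[scale.isna(), "dose_unit"].unique()
        raise ValueError(f"unknown dose_unit values: {list(bad)}")
    return scale.to_numpy(dtype=float)


def read_checkerboard_csv(path) -> Checkerboard:
    """Read and validate a long-format checkerboard CSV.

    Requires columns ``dose_a_nM, dose_b_nM, replicate`` and either
    ``viability`` (normalized) or ``signal`` (raw; normalized here
    against the double-vehicle wells).  Doses are nM unless a
    ``dose_unit`` column says otherwise.  Duplicate
    (dose_a, dose_b, replicate) rows and a missing (0, 0) vehicle well
    are rejected with row numbers.
    """
    df = pd.read_csv(path)
    needed = {"dose_a_nM", "dose_b_nM", "replicate"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_viab = "viability" in df.columns
    if not has_viab and "signal" not in df.columns:
        raise ValueError(f"{path}: need a 'viability' or 'signal' column")
    for col in ("dose_a_nM", "dose_b_nM"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = (df.index[vals.isna()] + 2).tolist()  # 1-based + header
            raise ValueError(f"{path}: non-numeric {col} at rows {rows}")
        df[col] = vals
    scale = _dose_scale(df)
    df["dose_a_nM"] = df["dose_a_nM"] * scale
    df["dose_b_nM"] = df["dose_b_nM"] * scale

    dup = df.duplicated(subset=["dose_a_nM", "dose_b_nM", "replicate"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate (dose_a, dose_b, replicate) rows {rows}")

    value_col = "viability" if has_viab else "signal"
    vehicle = df[(df["dose_a_nM"] == 0) & (df["dose_b_nM"] == 0)]
    if vehicle.empty:
        raise ValueError(f"{path}: no double-vehicle (0, 0) well present")

    doses_a = np.sort(df["dose_a_nM"].unique())
    doses_b = np.sort(df["dose_b_nM"].unique())
    reps = sorted(df["replicate"].unique())
    rep_index = {r: k for k, r in enumerate(reps)}
    ia = {d: i for i, d in enumerate(doses_a)}
    ib = {d: j for j, d in enumerate(doses_b)}
    cube = np.full((doses_a.size, doses_b.size, len(reps)), np.nan)
    for row in df.itertuples():
        cube[
            ia[getattr(row, "dose_a_nM")],
            ib[getattr(row, "dose_b_nM")],
            rep_index[row.replicate],
        ] = getattr(row, value_col)

    if not has_viab:
        vmean = float(vehicle["signal"].mean())
        if not (vmean > 0):
            raise ValueError(f"{path}: vehicle mean signal must be > 0, got {vmean}")
        cube = cube / vmean
        n_neg = int(np.sum(cube < 0))
        if n_neg:
            logger.warning("clipped %d negative normalized wells to 0", n_neg)
            cube = np.clip(cube, 0.0, None)
    return Checkerboard(doses_a, doses_b, cube)


def write_checkerboard_csv(board: Checkerboard, path) -> None:
    rows = []
    for i, da in enumerate(board.doses_a):
        for j, db in enumerate(board.doses_b):
            for r in range(board.n_replicates):
                v = board.viability[i, j, r]
                if np.isfinite(v):
                    rows.append((da, db, r + 1, v))
    pd.DataFrame(
        rows, columns=["dose_a_nM", "dose_b_nM", "replicate", "viability"]
    ).to_csv(path, index=False)


def read_dose_series_csv(path) -> dict[str, DoseSeries]:
    """Read single-agent series, one ``DoseSeries`` per ``drug`` value."""
    df = pd.read_csv(path)
    needed = {"drug", "dose_nM", "replicate"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_viab = "viability" in df.columns
    if not has_viab and "signal" not in df.columns:
        raise ValueError(f"{path}: need a 'viability' or 'signal' column")
    value_col = "viability" if has_viab else "signal"
    out = {}
    for drug, sub in df.groupby("drug"):
        doses = np.sort(sub["dose_nM"].unique())
        if doses.size == 0 or doses[0] != 0:
            raise ValueError(f"{path}: drug {drug!r} lacks zero-dose vehicle rows")
        reps = sorted(sub["replicate"].unique())
        mat = np.full((doses.size, len(reps)), np.nan)
        di = {d: i for i, d in enumerate(doses)}
        ri = {r: k for k, r in enumerate(reps)}
        for row in sub.itertuples():
            mat[di[getattr(row, "dose_nM")], ri[row.replicate]] = getattr(row, value_col)
        if has_viab:
            out[str(drug)] = DoseSeries(doses, mat, drug=str(drug))
        else:
            out[str(drug)] = normalize_viability(
                mat[1:], mat[0], doses=doses[1:], drug=str(drug)
            )
    return out


def _sigfig(x: float, n: int = 4):
    """Round to n significant digits; NaN becomes the 'NA' marker."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if x == 0:
        return 0.0
    return float(f"{x:.{n}g}")


def _report_payload(report: SynergyReport) -> dict:
    raw = {
        "ci": report.ci,
        "ci_point_nM": list(report.ci_point) if report.ci_point else None,
        "ci_min_isobole": report.ci_min_isobole,
        "blending": report.blending,
    }
    return {
        "ci": _sigfig(report.ci),
        "ci_point_nM": (
            [_sigfig(report.ci_point[0]), _sigfig(report.ci_point[1])]
            if report.ci_point
            else "NA"
        ),
        "ci_min_isobole": _sigfig(report.ci_min_isobole),
        "blending": _sigfig(report.blending),
        "label": report.label,
        "basis": report.basis,
        "diagnostics": report.diagnostics,
        "cell_line": report.cell_line,
        "raw": raw,
    }


class _NanToNullEncoder(json.JSONEncoder):
    def default(self, o):  # numpy scalars
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _sanitize_nan(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return "NA"
    if isinstance(obj, dict):
        return {k: _sanitize_nan(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize_nan(v) for v in obj]
    return obj


def write_report(report: SynergyReport, path, format: str = "json") -> None:
    """Serialize a synergy report to JSON (full) or a panel-style CSV row."""
    if format == "json":
        payload = _sanitize_nan(_report_payload(report))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, cls=_NanToNullEncoder, allow_nan=False)
            fh.write("\n")
    elif format == "csv":
        pd.DataFrame(
            [
                {
                    "cell_line": report.cell_line,
                    "meaning": report.label.capitalize(),
                    "blending_synergy": _sigfig(report.blending),
                    "combination_index": _sigfig(report.ci),
                }
            ]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _na_to_nan(x):
    return math.nan if x == "NA" else x


def read_report(path) -> SynergyReport:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    raw = data.get("raw", {})

    def pick(key):
        v = raw.get(key, data.get(key))
        return _na_to_nan(v) if not isinstance(v, list) else v

    ci = pick("ci")
    point = raw.get("ci_point_nM")
    return SynergyReport(
        ci=ci if ci is not None else math.nan,
        ci_point=tuple(point) if point else None,
        ci_min_isobole=pick("ci_min_isobole"),
        blending=pick("blending"),
        label=data["label"],
        basis=data["basis"],
        diagnostics=data.get("diagnostics", {}),
        cell_line=data.get("cell_line", ""),
    )


def load_table1() -> pd.DataFrame:
    """The packaged 15-cell-line synergy panel (printed values, NA markers)."""
    with resources.files("combosurf.data").joinpath(
        "table1_synergy_panel.csv"
    ).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    df["combination_index"] = pd.to_numeric(
        df["combination_index"].replace("NA", np.nan)
    )
    return df


def run_table1_check(rows: pd.DataFrame | None = None) -> dict:
    """Re-apply the classifier to the printed panel values.

    Each row's printed (blending, CI-or-NA) pair is classified with the
    published thresholds and compared against the printed meaning.
    Returns agreement counts, per-label tallies, and any mismatches.
    """
    df = load_table1() if rows is None else rows.copy()
    needed = {"cell_line", "meaning", "blending_synergy", "combination_index"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"panel rows missing columns: {sorted(missing)}")
    tallies = {label: 0 for label in ("synergy", "additivity", "subadditivity")}
    mismatches = []
    for row in df.itertuples():
        ci = row.combination_index
        ci = None if (ci is None or (isinstance(ci, float) and math.isnan(ci))) else float(ci)
        label, basis = classify(ci, float(row.blending_synergy))
        tallies[label] += 1
        printed = str(row.meaning).strip().lower()
        printed = LABEL_ALIASES.get(printed, printed)
        if label != printed:
            mismatches.append(
                {"cell_line": row.cell_line, "printed": row.meaning,
                 "computed": label, "basis": basis}
            )
    return {
        "n_rows": int(len(df)),
        "n_agree": int(len(df) - len(mismatches)),
        "per_label": tallies,
        "mismatches": mismatches,
    }
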