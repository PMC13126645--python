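"""Readers and writers for the package's plain-text data dialects.

All tabular files are comma-separated UTF-8 with '.' decimal separator
and a mandatory header row (plate readers export regional dialects;
this package reads exactly one).  SAXS curves use the community
3-column ASCII convention (q, I, sigma) with '#' comments.  Result
files are JSON and embed enough metadata (seed, package version,
config hash) to regenerate them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import TitrationPoint
from .dissociation import DecaySeries
from .errors import ParameterError, ParseError
from .kinetics import KineticTrace
from .mds import SizingMeasurement, clip_fraction
from .saxs import ScatteringCurve

__all__ = [
    "RunConfig", "load_run_config",
    "read_plate_csv", "write_plate_csv",
    "read_mds_csv", "write_mds_csv",
    "read_titration_csv", "write_titration_csv",
    "read_decay_csv", "write_decay_csv",
    "read_saxs_dat", "write_saxs_dat",
    "write_result_json", "read_result_json",
]

_TIME_FACTORS = {"h": 1.0, "hours": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}


@dataclass
class RunConfig:
    """Structured run configuration loaded from YAML.

    ``scenario`` selects synthetic mode; ``inputs`` maps stream names to
    file paths for real-data mode (paths must exist).  ``time_unit``
    declares the unit of plate-reader time columns.
    """

    scenario: str | None = None
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    time_unit: str = "h"
    noise: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    outdir: str = "."
    verbosity: int = 0

    def __post_init__(self):
        if self.time_unit not in _TIME_FACTORS:
            raise ParseError(f"unknown time unit {self.time_unit!r}")
        if self.scenario is None:
            for name, p in self.inputs.items():
                if not Path(p).exists():
                    raise ParseError(f"input {name!r}: path {p} does not exist")


def load_run_config(path) -> RunConfig:
    """Read a YAML run configuration (unknown keys are rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises many flavours
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.empty:
        raise ParseError(f"{path}: empty table")
    return df


def read_plate_csv(path, time_unit: str = "h", well_map: dict | None = None) -> list:
    """Plate-reader export: one ``time`` column + one column per well.

    ``time_unit`` declares the stored unit (s/min/h); times are
    converted to hours.  ``well_map`` maps well column names to
    chaperone concentrations (nM); unmapped wells get 0 nM.
    """
    if time_unit not in _TIME_FACTORS:
        raise ParseError(f"unknown time unit {time_unit!r}")
    df = _read_csv(path)
    if "time" not in df.columns:
        raise ParseError(f"{path}: missing 'time' column")
    t = pd.to_numeric(df["time"], errors="coerce").to_numpy() * _TIME_FACTORS[time_unit]
    if np.any(~np.isfinite(t)):
        bad = int(np.nonzero(~np.isfinite(t))[0][0])
        raise ParseError(f"{path}: non-numeric time at row {bad + 2}")
    dec = np.nonzero(np.diff(t) <= 0)[0]
    if dec.size:
        raise ParseError(f"{path}: time not strictly increasing at row {int(dec[0]) + 3}")
    traces = []
    for col in df.columns:
        if col == "time":
            continue
        y = pd.to_numeric(df[col], errors="coerce").to_numpy()
        if np.any(~np.isfinite(y)):
            bad = int(np.nonzero(~np.isfinite(y))[0][0])
            raise ParseError(f"{path}: non-numeric value in well {col} row {bad + 2}")
        conc = float(well_map.get(col, 0.0)) if well_map else 0.0
        traces.append(KineticTrace(t=t, signal=y, well_id=str(col), jb6_conc=conc))
    if not traces:
        raise ParseError(f"{path}: no well columns")
    return traces


def write_plate_csv(path, traces, time_unit: str = "h") -> None:
    t = traces[0].t
    for tr in traces[1:]:
        if not np.array_equal(tr.t, t):
            raise ParameterError("all traces must share one time grid")
    df = pd.DataFrame({"time": t / _TIME_FACTORS[time_unit]})
    for tr in traces:
        df[tr.well_id] = tr.signal
    df.to_csv(path, index=False)


def read_mds_csv(path) -> list:
    """MDS export: columns replicate_id, size_range and either
    diffused_fraction or the intensity pair intensity_inlet /
    intensity_diffused.  Fractions above 0.5 are QC-clipped with a
    warning; negative intensities are an error."""
    df = _read_csv(path)
    out = []
    for i, row in df.iterrows():
        rid = str(row.get("replicate_id", i))
        srange = int(row.get("size_range", 3))
        if "diffused_fraction" in df.columns and pd.notna(row.get("diffused_fraction")):
            f = float(row["diffused_fraction"])
            if f < 0:
                raise ParseError(f"{path}: negative diffused fraction at row {i + 2}")
            out.append(
                SizingMeasurement(
                    diffused_fraction=clip_fraction(f), replicate_id=rid,
                    size_range_id=srange,
                )
            )
        else:
            try:
                ii = float(row["intensity_inlet"])
                idf = float(row["intensity_diffused"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: row {i + 2} lacks intensities/fraction") from exc
            if ii < 0 or idf < 0:
                raise ParseError(f"{path}: negative intensity at row {i + 2}")
            out.append(
                SizingMeasurement.from_intensities(
                    ii, idf, replicate_id=rid, size_range_id=srange
                )
            )
    return out


def write_mds_csv(path, measurements) -> None:
    pd.DataFrame(
        {
            "replicate_id": [m.replicate_id for m in measurements],
            "size_range": [m.size_range_id for m in measurements],
            "intensity_inlet": [m.intensity_inlet for m in measurements],
            "intensity_diffused": [m.intensity_diffused for m in measurements],
            "diffused_fraction": [m.diffused_fraction for m in measurements],
        }
    ).to_csv(path, index=False)


def read_titration_csv(path) -> list:
    """Titration table: columns X (volume fraction, or X_percent), f,
    replicate_id."""
    df = _read_csv(path)
    if "X" in df.columns:
        X = pd.to_numeric(df["X"], errors="coerce")
    elif "X_percent" in df.columns:
        X = pd.to_numeric(df["X_percent"], errors="coerce") / 100.0
    else:
        raise ParseError(f"{path}: missing X (or X_percent) column")
    if "f" not in df.columns:
        raise ParseError(f"{path}: missing f column")
    f = pd.to_numeric(df["f"], errors="coerce")
    if X.isna().any() or f.isna().any():
        raise ParseError(f"{path}: non-numeric X or f values")
    rid = df["replicate_id"] if "replicate_id" in df.columns else df.index.astype(str)
    return [
        TitrationPoint(X=float(x), f=float(clip_fraction(ff)), replicate_id=str(r))
        for x, ff, r in zip(X, f, rid)
    ]


def write_titration_csv(path, points) -> None:
    pd.DataFrame(
        {
            "X": [p.X for p in points],
            "f": [p.f for p in points],
            "replicate_id": [p.replicate_id for p in points],
        }
    ).to_csv(path, index=False)


def read_decay_csv(path) -> list:
    """Decay table: columns t_h, r_h_nm, optional sd_nm, condition,
    temperature; returns one DecaySeries per (condition, temperature)."""
    df = _read_csv(path)
    for col in ("t_h", "r_h_nm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing {col} column")
    df["condition"] = df.get("condition", "without_JB6")
    df["temperature"] = df.get("temperature", "37C")
    out = []
    for (cond, temp), grp in df.groupby(["condition", "temperature"], sort=True):
        grp = grp.sort_values("t_h")
        sd = None
        if "sd_nm" in grp.columns and grp["sd_nm"].notna().all():
            sd = grp["sd_nm"].to_numpy(float)
        out.append(
            DecaySeries(
                t=grp["t_h"].to_numpy(float), r_h=grp["r_h_nm"].to_numpy(float),
                sd=sd, condition=str(cond), temperature_label=str(temp),
            )
        )
    return out


def write_decay_csv(path, series_list) -> None:
    frames = []
    for s in series_list:
        d = {"t_h": s.t, "r_h_nm": s.r_h, "condition": s.condition,
             "temperature": s.temperature_label}
        if s.sd is not None:
            d["sd_nm"] = s.sd
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_saxs_dat(path) -> ScatteringCurve:
    """3-column ASCII (q, I, sigma), whitespace-separated, '#' comments."""
    try:
        arr = np.loadtxt(path, comments="#", ndmin=2)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse SAXS file ({exc})") from exc
    if arr.shape[1] < 2:
        raise ParseError(f"{path}: need at least q and I columns")
    q, I = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    order = np.argsort(q)
    return ScatteringCurve(
        q=q[order], I=I[order], sigma=None if sigma is None else sigma[order]
    )


def write_saxs_dat(path, curve: ScatteringCurve, header: str = "") -> None:
    cols = [curve.q, curve.I]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    head = (header + "\n" if header else "") + "q_invA I sigma"
    np.savetxt(path, np.column_stack(cols), header=head)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_result_json(path, payload: dict, *, seed=None, config: dict | None = None) -> None:
    """Write a result dict with reproducibility metadata attached."""
    out = dict(payload)
    out["_meta"] = {
        "tool": "oligokin",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config or {}),
        "config": config or {},
    }
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if hasattr(x, "__dict__"):
        return {k: v for k, v in vars(x).items() if not k.startswith("_")}
    return str(x)


def read_result_json(path) -> dict:
    return json.loads(Path(path).read_text())
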