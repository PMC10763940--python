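"""File formats: calibration models as JSON, layouts/features/reports as CSV.

All writers stamp a ``schema_version`` so persisted artifacts remain
readable as the formats evolve; readers reject unknown versions.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import pandas as pd

from .calibration import CalibrationCurve
from .plate import PlateGeometry, PlateLayout, WellAssignment

SCHEMA_VERSION = "1"

FEATURE_COLUMNS = ["well", "mean_r", "mean_g", "mean_b", "composite_rgb", "n_pixels"]
LAYOUT_COLUMNS = ["well", "role", "conc_ppb", "sample_id"]

__all__ = [
    "SCHEMA_VERSION",
    "save_model",
    "load_model",
    "write_features",
    "read_features",
    "write_layout",
    "read_layout",
    "write_report",
]


def save_model(
    model: CalibrationCurve,
    path: str | Path,
    channel: str = "mean_r",
    seed: int | None = None,
) -> None:
    """Persist a fitted calibration as JSON (full precision)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "channel": channel,
        "slope": model.slope_,
        "intercept": model.intercept_,
        "se_slope": model.se_slope_,
        "se_intercept": model.se_intercept_,
        "r2": model.r2_,
        "adj_r2": model.adj_r2_,
        "residual_sd": model.residual_sd_,
        "n": model.n_,
        "linear_lo": model.linear_lo_,
        "linear_hi": model.linear_hi_,
        "lod_ppb": model.lod_ppb_,
        "loq_ppb": model.loq_ppb_,
        "sigma_mode": model.sigma_mode,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def load_model(path: str | Path) -> tuple[CalibrationCurve, dict]:
    """Load a persisted calibration; returns (model, full metadata dict)."""
    meta = json.loads(Path(path).read_text())
    if str(meta.get("schema_version")) != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema_version: {meta.get('schema_version')!r}")
    model = CalibrationCurve.from_parameters(
        slope=meta["slope"],
        intercept=meta["intercept"],
        se_slope=meta.get("se_slope", 0.0),
        se_intercept=meta.get("se_intercept", 0.0),
        r2=meta.get("r2", float("nan")),
        adj_r2=meta.get("adj_r2", float("nan")),
        residual_sd=meta.get("residual_sd", 0.0),
        n=meta.get("n", 0),
        linear_range=(meta["linear_lo"], meta["linear_hi"]),
        sigma_mode=meta.get("sigma_mode", "slope_se"),
    )
    return model, meta


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features[FEATURE_COLUMNS].to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV missing columns: {sorted(missing)}")
    return df


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    rows = []
    for label in layout.labels():
        a = layout.wells[label]
        rows.append(
            {
                "well": label,
                "role": a.role,
                "conc_ppb": a.conc_ppb,
                "sample_id": a.sample_id,
            }
        )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)


def read_layout(path: str | Path, geometry: PlateGeometry) -> PlateLayout:
    """Read a well,role,conc_ppb,sample_id CSV; geometry is supplied by the
    caller (it describes the scan, not the sample sheet)."""
    df = pd.read_csv(path)
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
    wells = {}
    for _, row in df.iterrows():
        conc = row["conc_ppb"]
        sid = row["sample_id"]
        wells[str(row["well"])] = WellAssignment(
            role=str(row["role"]),
            conc_ppb=None if pd.isna(conc) else float(conc),
            sample_id=None if pd.isna(sid) else str(sid),
        )
    return PlateLayout(geometry=geometry, wells=wells)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False)
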