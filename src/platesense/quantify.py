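"""Invert a calibration to concentrations and apply the reporting rules.

A measured response is mapped to concentration by solving the calibration
line for X: conc = (response - intercept) / slope.  Predictions outside the
validated linear range are reported as N.D. (non-detectable) rather than as
numbers; the range is a closed interval, so a response mapping exactly onto
an endpoint is still reportable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .plate import PlateLayout

ND = "ND"
OK = "OK"

__all__ = ["Prediction", "predict_concentration", "batch_predict", "predictions_to_frame"]


@dataclass(frozen=True)
class Prediction:
    """One quantified sample.

    conc_ppb is held at full precision (round only for display); it is None
    exactly when status == "ND".  raw_ppb always carries the uninverted value,
    including out-of-range ones, for diagnostics.
    """

    sample_id: str
    response: float
    conc_ppb: float | None
    status: str
    range_used: tuple[float, float]
    raw_ppb: float

    @property
    def is_nd(self) -> bool:
        return self.status == ND


def predict_concentration(
    model: CalibrationCurve, response: float, sample_id: str = ""
) -> Prediction:
    """Quantify one response; N.D. when the inverted concentration leaves the
    validated linear range (closed interval at both endpoints)."""
    if not math.isfinite(response):
        raise ValueError("non-finite response")
    raw = float(model.inverse(response))
    lo, hi = model.linear_lo_, model.linear_hi_
    if lo <= raw <= hi:
        return Prediction(
            sample_id=sample_id,
            response=float(response),
            conc_ppb=raw,
            status=OK,
            range_used=(lo, hi),
            raw_ppb=raw,
        )
    return Prediction(
        sample_id=sample_id,
        response=float(response),
        conc_ppb=None,
        status=ND,
        range_used=(lo, hi),
        raw_ppb=raw,
    )


def batch_predict(
    model: CalibrationCurve,
    features: pd.DataFrame,
    layout: PlateLayout | None = None,
    channel: str = "mean_r",
) -> list[Prediction]:
    """Quantify every unknown sample in a feature table.

    With a layout, feature rows are matched to the layout's unknown wells by
    well label and grouped by sample id; without one, the table must carry a
    ``sample_id`` column.  Replicate wells are averaged on the response scale
    before inversion.  Results are ordered by sample id.
    """
    if features.empty:
        return []
    if channel not in features.columns:
        raise ValueError(f"feature table lacks channel column {channel!r}")
    if layout is not None:
        known = set(features["well"])
        groups: dict[str, list[float]] = {}
        for label in layout.labels():
            a = layout.wells[label]
            if a.role != "unknown":
                continue
            if label not in known:
                raise ValueError(f"layout well {label} missing from feature table")
            resp = features.loc[features["well"] == label, channel]
            groups.setdefault(str(a.sample_id), []).extend(resp.tolist())
    else:
        if "sample_id" not in features.columns:
            raise ValueError("need a layout or a sample_id column")
        groups = {
            str(sid): grp[channel].tolist()
            for sid, grp in features.groupby("sample_id")
        }
    return [
        predict_concentration(model, float(np.mean(vals)), sample_id=sid)
        for sid, vals in sorted(groups.items())
    ]


def predictions_to_frame(
    predictions: Sequence[Prediction], nd_literal: str = "N.D.", decimals: int = 3
) -> pd.DataFrame:
    """Report table: sample_id, response, conc_ppb (rounded; N.D. literal), status."""
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "response": p.response,
                "conc_ppb": nd_literal if p.is_nd else round(p.conc_ppb, decimals),
                "status": nd_literal if p.is_nd else p.status,
            }
            for p in predictions
        ]
    )
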