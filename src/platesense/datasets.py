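"""Bundled reference data for the Cr(VI) plate assay.

* The published calibration constants of the two instruments (plate imager
  red-channel line and the benchtop spectrophotometer line at 650 nm).
* A 27-sample river-water survey measured by both instruments, used for the
  worked inter-method comparison.  Missing ``uiis_index``/``plate_ppb``
  entries are samples the plate imager reported as N.D. (outside its
  validated 25-600 ppb range).
* The spike-recovery experiment (50-500 ppb spikes into ultrapure water).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import CalibrationCurve

#: Plate-imager red-channel calibration: R = slope * ppb + intercept,
#: validated linear range 25-600 ppb, sigma = slope SE for LOD/LOQ.
PLATE_CALIBRATION = {
    "slope": -0.06134,
    "se_slope": 0.00222,
    "intercept": 100.49757,
    "se_intercept": 0.63949,
    "adj_r2": 0.99216,
    "linear_range": (25.0, 600.0),
}

#: Spectrophotometer calibration: absorbance(650 nm) = slope * ppb + intercept,
#: linear over 1-1000 ppb.
SPECTRO_CALIBRATION = {
    "slope": 2.55744e-4,
    "se_slope": 6.25491e-6,
    "intercept": -0.00178,
    "se_intercept": 0.00281,
    "adj_r2": 0.994,
    "linear_range": (1.0, 1000.0),
}

#: Spike-recovery experiment: spiked ppb -> published recovery %.
RECOVERY_EXPERIMENT = {50.0: 101.056, 100.0: 100.026, 250.0: 100.0324, 500.0: 99.9716}

__all__ = [
    "PLATE_CALIBRATION",
    "SPECTRO_CALIBRATION",
    "RECOVERY_EXPERIMENT",
    "plate_calibration_model",
    "spectro_calibration_model",
    "load_river_survey",
]


def _model(constants: dict, sigma_mode: str = "slope_se") -> CalibrationCurve:
    return CalibrationCurve.from_parameters(
        slope=constants["slope"],
        intercept=constants["intercept"],
        se_slope=constants["se_slope"],
        se_intercept=constants["se_intercept"],
        adj_r2=constants["adj_r2"],
        linear_range=constants["linear_range"],
        sigma_mode=sigma_mode,
    )


def plate_calibration_model(sigma_mode: str = "slope_se") -> CalibrationCurve:
    """The plate imager's red-channel calibration as a fitted model."""
    return _model(PLATE_CALIBRATION, sigma_mode)


def spectro_calibration_model(sigma_mode: str = "slope_se") -> CalibrationCurve:
    """The spectrophotometer's absorbance calibration as a fitted model."""
    return _model(SPECTRO_CALIBRATION, sigma_mode)


def load_river_survey() -> pd.DataFrame:
    """The 27-sample river-water survey (both instruments' read-outs)."""
    with resources.files("platesense.data").joinpath("river_survey.csv").open() as fh:
        return pd.read_csv(fh)
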