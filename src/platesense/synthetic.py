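"""Synthetic data generation with known ground truth.

Everything the pipeline consumes — plate scans, pooled calibration tables,
kinetic series, reagent dose-response curves, ion panels — can be generated
here under a mandatory seed, so every stage is testable end to end without
any instrument.

The generative model mirrors the assay:

* the red channel of a well responds linearly to Cr(VI) concentration
  (mean R = slope * conc + intercept; the blue oxidation product absorbs
  red light, so the slope is negative),
* green and blue channels carry a near-zero slope plus noise — they are
  deliberately uninformative, so channel selection is exercised realistically,
* noise enters at two scales: a per-well Gaussian term (replicate-to-replicate
  chemistry/illumination variation, default sd 0.5 on the 0-255 scale) and a
  per-pixel Gaussian term (sensor noise, default sd 2.0),
* color development over time follows a saturating-exponential profile
  f(t) = 1 - exp(-3 t / t*), which passes 95 % of its asymptote at t = t*,
* reagent dose-response follows a Michaelis-type saturation
  r(d) = Rmax * d / (k + d).

Rendered wells are quantized to 8 bits; truth tables record both the analog
model mean (``target_mean_*``) and the quantized pre-pixel-noise rendered
mean (``rendered_mean_*``), which differ by at most half an intensity step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import DoseResponseSeries, KineticSeries
from .plate import (
    PlateGeometry,
    PlateImage,
    PlateLayout,
    WellAssignment,
    well_labels,
)

#: Reference truth for the red-channel calibration used throughout examples
#: and tests: the assay's published slope/intercept on the 0-255 R scale.
DEFAULT_SLOPE_R = -0.06134
DEFAULT_INTERCEPT_R = 100.49757

#: The ten standard concentrations (ppb) of the calibration experiment.
DEFAULT_CONCENTRATIONS = (1.0, 25.0, 50.0, 75.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0)

__all__ = [
    "GeneratorConfig",
    "make_standard_layout",
    "generate_plate_image",
    "generate_calibration_table",
    "generate_channel_feature_table",
    "development_fraction",
    "generate_kinetics",
    "generate_dose_response",
    "generate_ion_panel",
    "TMB_DOSE_PRESET",
    "H2O2_DOSE_PRESET",
    "DEFAULT_SLOPE_R",
    "DEFAULT_INTERCEPT_R",
    "DEFAULT_CONCENTRATIONS",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of the simulated assay.  ``seed`` is mandatory."""

    seed: int
    slope_r: float = DEFAULT_SLOPE_R
    intercept_r: float = DEFAULT_INTERCEPT_R
    slope_g: float = -0.0014
    intercept_g: float = 95.0
    slope_b: float = -0.0008
    intercept_b: float = 90.0
    well_noise_sd: float = 0.5
    pixel_noise_sd: float = 2.0
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    replicates: int = 9
    # plate rendering geometry (pixels)
    well_spacing_px: float = 30.0
    well_radius_px: float = 12.0
    margin_px: float = 20.0
    dpi: float = 150.0
    background_rgb: tuple[int, int, int] = (30, 30, 30)
    kinetic_t_star_min: float = 15.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def channel_truth(self, channel: str) -> tuple[float, float]:
        return {
            "r": (self.slope_r, self.intercept_r),
            "g": (self.slope_g, self.intercept_g),
            "b": (self.slope_b, self.intercept_b),
        }[channel]


def make_standard_layout(config: GeneratorConfig) -> PlateLayout:
    """Row-major layout of calibration standards: each concentration gets
    ``config.replicates`` wells; leftover wells are blanks."""
    n_std = len(config.concentrations) * config.replicates
    if n_std > 96:
        raise ValueError(f"{n_std} standard wells do not fit a 96-well plate")
    geom = PlateGeometry(
        x0=config.margin_px + config.well_radius_px,
        y0=config.margin_px + config.well_radius_px,
        dx=config.well_spacing_px,
        dy=config.well_spacing_px,
        well_radius=config.well_radius_px,
    )
    wells: dict[str, WellAssignment] = {}
    labels = well_labels()
    i = 0
    for conc in config.concentrations:
        for _ in range(config.replicates):
            wells[labels[i]] = WellAssignment(role="standard", conc_ppb=float(conc))
            i += 1
    for label in labels[i:]:
        wells[label] = WellAssignment(role="blank")
    return PlateLayout(geometry=geom, wells=wells)


def _well_conc(assignment: WellAssignment) -> float:
    return assignment.conc_ppb if assignment.role == "standard" else 0.0


def generate_plate_image(
    config: GeneratorConfig,
    layout: PlateLayout | None = None,
    unknown_concs: dict[str, float] | None = None,
) -> tuple[PlateImage, pd.DataFrame]:
    """Render a plate scan plus its ground-truth table.

    Unknown wells are rendered at the concentration given in
    ``unknown_concs`` (keyed by sample id); blanks at 0 ppb.  The truth
    table has one row per assigned well with the true concentration, the
    analog channel means and the quantized rendered means.

    Raises ValueError if any analog channel mean leaves [0, 255] before
    noise (the offending concentration is named).
    """
    if layout is None:
        layout = make_standard_layout(config)
    unknown_concs = unknown_concs or {}
    rng = config.rng()
    geom = layout.geometry
    width = int(np.ceil(geom.x0 + (layout.n_cols - 1) * geom.dx + geom.well_radius + config.margin_px))
    height = int(np.ceil(geom.y0 + (layout.n_rows - 1) * geom.dy + geom.well_radius + config.margin_px))
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = np.array(config.background_rgb, dtype=np.uint8)

    ys, xs = np.mgrid[0:height, 0:width]
    rows = []
    for label in layout.labels():
        a = layout.wells[label]
        if a.role == "unknown":
            if a.sample_id not in unknown_concs:
                raise ValueError(f"no concentration given for sample {a.sample_id!r}")
            conc = float(unknown_concs[a.sample_id])
        else:
            conc = _well_conc(a)
        cx, cy = layout.center(label)
        mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= geom.well_radius**2
        row = {"well": label, "role": a.role, "sample_id": a.sample_id, "conc_ppb": conc}
        for ch, ci in (("r", 0), ("g", 1), ("b", 2)):
            slope, intercept = config.channel_truth(ch)
            target = slope * conc + intercept
            if not 0.0 <= target <= 255.0:
                raise ValueError(
                    f"channel {ch} mean {target:.2f} at {conc} ppb leaves [0, 255]; "
                    "reduce the concentration range"
                )
            noisy = target + (rng.normal(0.0, config.well_noise_sd) if config.well_noise_sd > 0 else 0.0)
            rendered = int(np.clip(np.rint(noisy), 0, 255))
            img[mask, ci] = rendered
            row[f"target_mean_{ch}"] = target
            row[f"rendered_mean_{ch}"] = float(rendered)
        rows.append(row)

    if config.pixel_noise_sd > 0:
        noise = rng.normal(0.0, config.pixel_noise_sd, size=img.shape)
        img = np.clip(np.rint(img.astype(float) + noise), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(rows)
    return PlateImage(pixels=img, dpi=config.dpi), truth


def generate_calibration_table(
    config: GeneratorConfig, wells_per_conc: int = 50
) -> pd.DataFrame:
    """Pooled replicate calibration data, bypassing the imaging step.

    Emulates the repeated-well calibration experiment at the response level:
    one row per well with columns conc_ppb and response (mean R), response =
    slope * conc + intercept + per-well Gaussian noise.
    """
    rng = config.rng()
    concs = np.repeat(np.asarray(config.concentrations, dtype=float), wells_per_conc)
    resp = config.slope_r * concs + config.intercept_r
    resp = resp + rng.normal(0.0, config.well_noise_sd, size=concs.size)
    return pd.DataFrame({"conc_ppb": concs, "response": resp})


def development_fraction(
    t: np.ndarray | float, t_star: float, t_onset: float | None = None
) -> np.ndarray:
    """Color-development profile: flat until onset, then saturating exponential.

    f(t) = 0 for t <= t_onset and 1 - exp(-3 (t - t_onset)/(t* - t_onset))
    after, so f(t*) = 1 - e^-3 ~ 0.95 and f -> 1.  The flat lead-in mirrors
    the assay's negligible color change before development begins; onset
    defaults to 2/3 of t*.
    """
    t = np.asarray(t, dtype=float)
    if t_onset is None:
        t_onset = 2.0 * t_star / 3.0
    if not 0 <= t_onset < t_star:
        raise ValueError("need 0 <= t_onset < t_star")
    return np.where(
        t <= t_onset, 0.0, 1.0 - np.exp(-3.0 * (t - t_onset) / (t_star - t_onset))
    )


def generate_kinetics(
    config: GeneratorConfig,
    times_min: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0),
    concentrations: tuple[float, ...] | None = None,
) -> KineticSeries:
    """Kinetic read-out of the red channel at several times and concentrations.

    response(t, X) = intercept + slope * X * f(t) + noise, with f the
    saturating development profile reaching 95 % at t* =
    ``config.kinetic_t_star_min``.  At t = 0 every concentration reads the
    intercept (no color yet).
    """
    times = np.asarray(times_min, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    t_star = config.kinetic_t_star_min
    if not times.min() <= t_star <= times.max():
        raise ValueError("saturation time t* must lie within the time grid")
    concs = np.asarray(
        concentrations if concentrations is not None else config.concentrations,
        dtype=float,
    )
    rng = config.rng()
    f = development_fraction(times, t_star)[:, None]
    resp = config.intercept_r + config.slope_r * concs[None, :] * f
    if config.well_noise_sd > 0:
        resp = resp + rng.normal(0.0, config.well_noise_sd, size=resp.shape)
    return KineticSeries(times=times, concs=concs, responses=resp)


def generate_channel_feature_table(
    config: GeneratorConfig, wells_per_conc: int = 9
) -> pd.DataFrame:
    """Well-level RGB feature table for the channel-selection study.

    One row per replicate well with conc_ppb, mean_r, mean_g, mean_b and
    composite_rgb; each channel follows its own truth line plus independent
    per-well noise (the red channel carries the signal, green and blue are
    nearly flat).
    """
    rng = config.rng()
    concs = np.repeat(np.asarray(config.concentrations, dtype=float), wells_per_conc)
    cols = {"conc_ppb": concs}
    for ch in ("r", "g", "b"):
        slope, intercept = config.channel_truth(ch)
        cols[f"mean_{ch}"] = (
            slope * concs + intercept
            + rng.normal(0.0, config.well_noise_sd, size=concs.size)
        )
    df = pd.DataFrame(cols)
    df["composite_rgb"] = df["mean_r"] + df["mean_g"] + df["mean_b"]
    return df


# -- reagent dose-response presets ------------------------------------------
# Chromogen (TMB) titration: 0.1-1.5 mM grid; half-saturation constant chosen
# so the 5 %-of-plateau crossing falls between the 0.8 and 0.9 mM samples,
# and amplitude scaled so absorbances stay inside the 0.0047-0.0685 AU band
# observed for this titration.
TMB_DOSE_PRESET = {
    "doses": tuple(np.round(np.arange(0.1, 1.51, 0.1), 2)),
    "rmax": 0.0735,
    "k": 0.11,
}

# Oxidant (H2O2) titration: 10-300 mM grid, saturating from 50 mM, absorbances
# inside the 0.0243-0.1523 AU band.
H2O2_DOSE_PRESET = {
    "doses": (10.0, 20.0, 30.0, 40.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0),
    "rmax": 0.1537,
    "k": 2.8,
}


def generate_dose_response(
    kind: str,
    params: dict | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> DoseResponseSeries:
    """Reagent titration curve.

    kind "saturating": r(d) = rmax * d / (k + d); params rmax, k, doses
    (defaults to the chromogen preset).  kind "linear": r(d) = offset +
    gain * d; params gain, offset, doses.  Gaussian noise (sd ``noise_sd``)
    is opt-in and seeded.
    """
    if kind == "saturating":
        p = {**TMB_DOSE_PRESET, **(params or {})}
        doses = np.asarray(p["doses"], dtype=float)
        if p["rmax"] <= 0 or p["k"] <= 0:
            raise ValueError("rmax and k must be positive")
        resp = p["rmax"] * doses / (p["k"] + doses)
    elif kind == "linear":
        p = {"doses": TMB_DOSE_PRESET["doses"], "gain": 0.04, "offset": 0.0, **(params or {})}
        doses = np.asarray(p["doses"], dtype=float)
        resp = p["offset"] + p["gain"] * doses
    else:
        raise ValueError(f"unknown dose-response kind: {kind!r}")
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, size=resp.shape)
    return DoseResponseSeries(doses=doses, responses=resp)


def generate_ion_panel(
    seed: int,
    cr6_signal: float = 0.2435,
    blank_signal: float = 0.002,
    rel_signal: float = 0.05,
    noise_sd: float = 0.0,
    ions: tuple[str, ...] = ("Cr3+", "Pb2+", "As3+", "Hg2+", "Cd2+", "Ba2+", "SO4 2-", "HCO3-", "PO4 3-"),
) -> dict[str, float]:
    """Absorbance panel for a selectivity study: the target analyte gives a
    strong signal, each interfering ion only ``rel_signal`` of it."""
    rng = np.random.default_rng(seed)
    panel = {"blank": blank_signal, "Cr(VI)": cr6_signal}
    for ion in ions:
        s = blank_signal + rel_signal * (cr6_signal - blank_signal)
        if noise_sd > 0:
            s += rng.normal(0.0, noise_sd)
        panel[ion] = s
    return panel
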