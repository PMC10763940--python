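"""OLS calibration, detection limits, and the three selection procedures."""

import numpy as np
import pandas as pd
import pytest

from platesense import (
    DoseResponseSeries,
    KineticSeries,
    detection_limits,
    fit_linear,
    saturation_dose,
    select_channel,
    select_reading_time,
)
from platesense.datasets import PLATE_CALIBRATION, SPECTRO_CALIBRATION
from platesense.synthetic import (
    GeneratorConfig,
    H2O2_DOSE_PRESET,
    generate_channel_feature_table,
    generate_dose_response,
)

from conftest import ols_oracle

M2, C2 = PLATE_CALIBRATION["slope"], PLATE_CALIBRATION["intercept"]


class TestFitLinear:
    def test_collinear_points_recover_line_exactly(self):
        x = np.array([0.0, 50.0, 100.0])
        m = fit_linear(x, M2 * x + C2)
        assert m.slope_ == pytest.approx(M2, abs=1e-12)
        assert m.intercept_ == pytest.approx(C2, abs=1e-12)
        assert m.r2_ == pytest.approx(1.0, abs=1e-12)
        assert m.adj_r2_ == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_spectro_line_round_trips(self):
        x = np.array([1, 25, 50, 75, 100, 200, 400, 600, 800, 1000], float)
        m1, c1 = SPECTRO_CALIBRATION["slope"], SPECTRO_CALIBRATION["intercept"]
        m = fit_linear(x, m1 * x + c1)
        assert m.slope_ == pytest.approx(m1, abs=1e-10)
        assert m.intercept_ == pytest.approx(c1, abs=1e-10)

    def test_matches_normal_equations_oracle_on_random_data(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 40)
            x = rng.uniform(0, 1000, n)
            if np.unique(x).size < 2:
                continue
            y = rng.normal(0, 10, n) + rng.uniform(-1, 1) * x
            m = fit_linear(x, y)
            slope, intercept, ses, sei, r2 = ols_oracle(x, y)
            assert m.slope_ == pytest.approx(slope, abs=1e-10, rel=1e-10)
            assert m.intercept_ == pytest.approx(intercept, abs=1e-10, rel=1e-10)
            assert m.se_slope_ == pytest.approx(ses, abs=1e-10, rel=1e-10)
            assert m.se_intercept_ == pytest.approx(sei, abs=1e-10, rel=1e-10)
            assert m.r2_ == pytest.approx(r2, abs=1e-10)

    def test_agrees_with_scipy_linregress(self):
        """Independent library cross-check of coefficients and SEs."""
        from scipy import stats

        rng = np.random.default_rng(17)
        x = rng.uniform(0, 1000, 50)
        y = M2 * x + C2 + rng.normal(0, 0.5, 50)
        m = fit_linear(x, y)
        ref = stats.linregress(x, y)
        assert m.slope_ == pytest.approx(ref.slope, rel=1e-9)
        assert m.intercept_ == pytest.approx(ref.intercept, rel=1e-9)
        assert m.se_slope_ == pytest.approx(ref.stderr, rel=1e-8)
        assert m.se_intercept_ == pytest.approx(ref.intercept_stderr, rel=1e-8)
        assert m.r2_ == pytest.approx(ref.rvalue**2, rel=1e-9)

    def test_noise_degrades_adjusted_r2(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 600, 30)
        signal = fit_linear(x, M2 * x + C2 + rng.normal(0, 0.5, x.size))
        noise_only = fit_linear(x, C2 + rng.normal(0, 0.5, x.size))
        assert signal.adj_r2_ > 0.99
        assert noise_only.adj_r2_ < signal.adj_r2_

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError, match="3 calibration points"):
            fit_linear([0, 100], [1.0, 2.0])
        with pytest.raises(ValueError, match="identical"):
            fit_linear([5, 5, 5], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="finite"):
            fit_linear([0, 1, 2], [1.0, np.nan, 3.0])


class TestDetectionLimits:
    def test_published_slope_se_pair_rounds_to_printed_limits(self):
        lod, loq = detection_limits(-0.06134, 0.00222, rounded=True)
        assert (lod, loq) == (0.12, 0.36)

    def test_loq_lod_ratio_identity(self):
        lod, loq = detection_limits(-0.06134, 0.00222)
        assert loq / lod == pytest.approx(10.0 / 3.3, abs=1e-12)

    def test_zero_sigma_gives_zero_limits(self):
        assert detection_limits(2.0, 0.0) == (0.0, 0.0)

    def test_zero_slope_is_an_error(self):
        with pytest.raises(ValueError):
            detection_limits(0.0, 1.0)

    def test_scale_equivariance_leaves_lod_unchanged(self):
        """Multiplying all responses by k scales sigma and |slope| alike."""
        rng = np.random.default_rng(1)
        x = np.linspace(0, 600, 25)
        y = M2 * x + C2 + rng.normal(0, 0.5, x.size)
        base = fit_linear(x, y)
        scaled = fit_linear(x, 7.5 * y)
        assert scaled.lod_ppb_ == pytest.approx(base.lod_ppb_, rel=1e-9)
        assert scaled.loq_ppb_ == pytest.approx(base.loq_ppb_, rel=1e-9)


class TestChannelSelection:
    def test_red_signal_is_selected_with_expected_ranking(self):
        table = generate_channel_feature_table(GeneratorConfig(seed=2), wells_per_conc=9)
        best, report = select_channel(table)
        assert best == "mean_r"
        adj = report["adj_r2"]
        assert (
            adj["mean_r"] > adj["composite_rgb"] > adj["mean_g"] > adj["mean_b"]
        )

    def test_signal_injected_into_blue_selects_blue(self):
        config = GeneratorConfig(
            seed=2, slope_r=-0.0008, intercept_r=90.0, slope_b=-0.06134, intercept_b=100.5
        )
        best, _ = select_channel(generate_channel_feature_table(config))
        assert best == "mean_b"

    def test_exact_tie_prefers_declared_order(self):
        x = np.array([0.0, 100.0, 200.0, 300.0])
        signal = C2 + M2 * x
        table = pd.DataFrame(
            {
                "conc_ppb": x,
                "mean_r": signal,
                "mean_g": signal.copy(),  # exact duplicate of the red channel
                "mean_b": [50.0, 50.1, 49.9, 50.0],
            }
        )
        table["composite_rgb"] = table[["mean_r", "mean_g", "mean_b"]].sum(axis=1)
        best, report = select_channel(table)
        assert best == "mean_r"

    def test_too_few_levels_rejected(self):
        table = pd.DataFrame(
            {"conc_ppb": [0, 0, 100, 100], "mean_r": [1, 1, 2, 2],
             "mean_g": [1, 1, 2, 2], "mean_b": [1, 1, 2, 2],
             "composite_rgb": [3, 3, 6, 6]}
        )
        with pytest.raises(ValueError, match="3 concentration levels"):
            select_channel(table)


def _orthogonal_pattern(x, seed):
    """A zero-mean residual pattern uncorrelated with x (so adding a scaled
    copy leaves the fitted slope untouched and degrades fit monotonically)."""
    rng = np.random.default_rng(seed)
    p = rng.normal(0, 1, x.size)
    p -= p.mean()
    p -= (p @ (x - x.mean())) / np.sum((x - x.mean()) ** 2) * (x - x.mean())
    return p


class TestReadingTime:
    def test_flat_early_phase_then_declining_linearity_picks_first_developed(self):
        """Developed times ordered 15 > 20 > 25 by adjusted R^2 and an
        undeveloped flat phase before 15 min: the earliest developed,
        most-linear time wins."""
        concs = np.array([1, 25, 50, 75, 100, 200, 400, 600, 800, 1000], float)
        p = _orthogonal_pattern(concs, seed=3)
        flat = C2 + 0.02 * p
        rows = [
            flat,
            flat,
            C2 + M2 * concs + 4.0 * p,
            C2 + M2 * concs + 6.0 * p,
            C2 + M2 * concs + 8.0 * p,
        ]
        series = KineticSeries(times=[5, 10, 15, 20, 25], concs=concs, responses=np.array(rows))
        best, report = select_reading_time(series)
        assert best == 15.0
        adj = report["adj_r2"]
        assert adj[15.0] > adj[20.0] > adj[25.0]
        assert not report.loc[5.0, "developed"] and not report.loc[10.0, "developed"]

    def test_single_informative_time_is_returned(self):
        concs = np.array([0.0, 100.0, 200.0, 400.0])
        flat = np.full(4, C2)
        series = KineticSeries(
            times=[5, 15], concs=concs, responses=np.array([flat, C2 + M2 * concs])
        )
        best, _ = select_reading_time(series)
        assert best == 15.0

    def test_all_flat_advises_longer_incubation(self):
        concs = np.array([0.0, 100.0, 200.0, 400.0])
        flat = np.full(4, C2)
        series = KineticSeries(times=[5, 10], concs=concs, responses=np.array([flat, flat]))
        with pytest.raises(ValueError, match="incubate longer"):
            select_reading_time(series)


class TestSaturationDose:
    def test_chromogen_preset_saturates_at_0p9_mM(self):
        res = saturation_dose(generate_dose_response("saturating"))
        assert res.status == "saturated"
        assert res.dose == 0.9

    def test_oxidant_preset_saturates_at_50_mM(self):
        res = saturation_dose(generate_dose_response("saturating", params=H2O2_DOSE_PRESET))
        assert res.status == "saturated"
        assert res.dose == 50.0

    def test_linear_response_is_not_saturated(self):
        res = saturation_dose(generate_dose_response("linear"))
        assert res.status == "not_saturated"
        assert res.dose == 1.5  # top dose, with warning status

    def test_constant_response_saturates_at_smallest_dose(self):
        series = DoseResponseSeries(doses=[1, 2, 3, 4.0], responses=[0.1, 0.1, 0.1, 0.1])
        res = saturation_dose(series)
        assert res.status == "saturated"
        assert res.dose == 1.0

    def test_needs_at_least_four_doses(self):
        with pytest.raises(ValueError):
            saturation_dose(DoseResponseSeries(doses=[1, 2, 3.0], responses=[1, 2, 3.0]))
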