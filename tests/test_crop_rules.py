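"""Season metrics (RCLE, EVE/EVL, RCPN), calendar surfaces, decision rules."""

import numpy as np
import pytest

import phenocrop as pc
from phenocrop.crop_rules import (
    DEFAULT_THRESHOLDS,
    SeasonMetrics,
    ThresholdConfig,
    WheatCalendar,
    classify_season,
    estimate_wheat_calendar,
    maize_metrics,
    rice_metrics,
    wheat_metrics,
)
from phenocrop.intensity import SeasonWindow, segment_seasons, wavelet_spectrum, cropping_index
from phenocrop.pattern_codes import Crop
from phenocrop.preprocess import smooth_indices
from phenocrop.purity import Stratum

GRID = np.arange(-90, 456)


def _window(till=150, head=210):
    return SeasonWindow(till - 20, till, head, head + 50, 0.4)


class TestRiceMetrics:
    def test_constant_lswi_gives_zero_rcle(self):
        lswi = np.full(len(GRID), 0.25)
        evi2 = np.interp(GRID, [130, 150, 210, 260], [0.15, 0.2, 0.6, 0.2])
        lswi_min, lswi_max, rcle = rice_metrics(GRID, lswi, evi2, _window())
        assert rcle == 0.0 and lswi_min == 0.25

    def test_hand_computed_ratio(self):
        # LSWI range 0.2 over the window, EVI2 rise 0.4 -> RCLE = 0.5
        lswi = np.interp(GRID, [150, 210], [0.1, 0.3])
        evi2 = np.interp(GRID, [150, 210], [0.2, 0.6])
        *_, rcle = rice_metrics(GRID, lswi, evi2, _window())
        assert rcle == pytest.approx(0.5, abs=1e-6)

    def test_simulated_rice_pixel_satisfies_pure_rule(self):
        cycle = pc.CropCycleParams("rice", 140, 210, 130, 0.55, flood_lswi_level=0.25)
        idx = smooth_indices(pc.simulate_pixel(15, cycles=(cycle,), seed=0))
        (w,) = segment_seasons(idx.grid, idx.evi2, 1)
        lswi_min, _, rcle = rice_metrics(idx.grid, idx.lswi, idx.evi2, w)
        assert lswi_min > 0.1 and rcle < 0.42

    def test_non_positive_evi2_rise_is_undefined(self):
        lswi = np.full(len(GRID), 0.25)
        evi2 = np.full(len(GRID), 0.4)
        assert rice_metrics(GRID, lswi, evi2, _window()) is None


class TestWheatMetrics:
    CAL = WheatCalendar(heading_doy=120, early_growing_length=150)

    def test_constant_series_gives_zero(self):
        eve, evl = wheat_metrics(GRID, np.full(len(GRID), 0.3), self.CAL, 160)
        assert eve == 0.0 and evl == 0.0

    def test_hand_computed_sums(self):
        # seedling 0.2 -> heading 0.6 monotone, then fall to 0.25 at harvest:
        # EVE = (0.6-0.2)+(0.6-0.2) = 0.8; EVL = (0.6-0.25)+(0.6-0.25) = 0.7
        evi2 = np.interp(GRID, [-30, 120, 160], [0.2, 0.6, 0.25])
        eve, evl = wheat_metrics(GRID, evi2, self.CAL, 160)
        assert eve == pytest.approx(0.8, abs=1e-6)
        assert evl == pytest.approx(0.7, abs=1e-6)

    def test_simulated_winter_wheat_satisfies_pure_rule(self):
        idx = smooth_indices(pc.simulate_pixel(16, seed=0))
        (w,) = segment_seasons(idx.grid, idx.evi2, 1)
        eve, evl = wheat_metrics(idx.grid, idx.evi2, self.CAL, w.harvest_doy)
        assert eve > 0.32 and evl > 0.12

    def test_window_outside_span_is_undefined(self):
        cal = WheatCalendar(heading_doy=30, early_growing_length=200)  # seedling -170
        assert wheat_metrics(GRID, np.full(len(GRID), 0.3), cal, 80) is None


class TestMaizeMetrics:
    def test_flat_nmdi_gives_zero(self):
        assert maize_metrics(GRID, np.full(len(GRID), 0.6), (180, 220)) == 0.0

    def test_monotone_rise_gives_zero(self):
        nmdi = np.interp(GRID, [GRID[0], GRID[-1]], [0.4, 0.8])
        assert maize_metrics(GRID, nmdi, (180, 220)) == 0.0

    def test_hand_computed_rise_then_fall(self):
        # +0.005/day for 20 d then -0.005/day for 20 d with sigma = 0.01:
        # RCPN = (0.1 + 0) * 0.1 / (0 + 0.1 + 0.01) * 100 = 9.0909...
        nmdi = np.full(len(GRID), 0.5)
        sel = (GRID >= 180) & (GRID <= 220)
        nmdi[sel] = 0.5 + 0.005 * (20 - np.abs(np.arange(-20, 21)))
        rcpn = maize_metrics(GRID, nmdi, (180, 220), sigma=0.01)
        assert rcpn == pytest.approx(0.1 * 0.1 / 0.11 * 100, abs=1e-6)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            maize_metrics(GRID, np.full(len(GRID), 0.6), (220, 180))


class TestWheatCalendar:
    def test_intercept_only_surface(self):
        surfaces = {
            "winter": {"heading": (120.0, 0.0, 0.0), "egl": (150.0, 0.0, 0.0),
                       "domain": ((0.0, 90.0), (0.0, 5000.0))},
        }
        cal = estimate_wheat_calendar(33.0, 250.0, "winter", surfaces)
        assert (cal.heading_doy, cal.early_growing_length) == (120.0, 150.0)

    def test_planar_surface_matches_hand_value(self):
        surfaces = {
            "winter": {"heading": (100.0, 1.5, -0.01), "egl": (120.0, 0.5, 0.002),
                       "domain": ((20.0, 45.0), (0.0, 3000.0))},
        }
        cal = estimate_wheat_calendar(34.0, 500.0, "winter", surfaces)
        assert cal.heading_doy == pytest.approx(100 + 1.5 * 34 - 0.01 * 500)
        assert cal.early_growing_length == pytest.approx(120 + 0.5 * 34 + 0.002 * 500)

    def test_dispatch_between_wheat_types(self):
        w = estimate_wheat_calendar(40.0, 1500.0, "winter")
        s = estimate_wheat_calendar(40.0, 1500.0, "spring")
        assert w.wheat_type == "winter" and s.wheat_type == "spring"
        assert w.heading_doy != s.heading_doy

    def test_out_of_domain_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            cal = estimate_wheat_calendar(60.0, 250.0, "winter")
        assert cal.heading_doy == 120.0


class TestClassifySeason:
    def test_rice_rule_example(self):
        m = SeasonMetrics(lswi_min=0.25, lswi_max=0.3, rcle=0.3)
        assert classify_season(m, Stratum.PURE) == Crop.RICE

    def test_stratified_rcle_threshold(self):
        m = SeasonMetrics(lswi_min=0.25, lswi_max=0.3, rcle=0.5)
        assert classify_season(m, Stratum.PURE) == Crop.OTHER  # 0.5 >= 0.42
        assert classify_season(m, Stratum.SERIOUS) == Crop.RICE  # 0.5 < 0.62

    def test_stratified_eve_threshold(self):
        m = SeasonMetrics(eve=0.20, evl=0.30)
        assert classify_season(m, Stratum.PURE) == Crop.OTHER  # 0.20 <= 0.32
        assert classify_season(m, Stratum.SERIOUS) == Crop.WHEAT  # 0.20 > 0.16

    def test_conflict_resolved_by_largest_relative_margin(self):
        # rice margin: min(1.5, (0.42-0.2)/0.42=0.524) = 0.524
        # maize margin: (0.5-0.45)/0.45 = 0.111 -> rice wins
        m = SeasonMetrics(lswi_min=0.25, lswi_max=0.3, rcle=0.2, rcpn=0.5)
        assert classify_season(m, Stratum.PURE) == Crop.RICE
        # overwhelming RCPN flips it
        m2 = SeasonMetrics(lswi_min=0.25, lswi_max=0.3, rcle=0.2, rcpn=5.0)
        assert classify_season(m2, Stratum.PURE) == Crop.MAIZE

    def test_exact_tie_prefers_rice(self):
        # both margins exactly 1.0
        m = SeasonMetrics(lswi_min=0.25, lswi_max=0.3, rcle=0.42 * (1 - 1.0),
                          rcpn=0.45 * 2.0)
        label, margins = classify_season(m, Stratum.PURE, return_details=True)
        assert margins[Crop.RICE] == margins[Crop.MAIZE] == 1.0
        assert label == Crop.RICE

    def test_no_rule_fires_gives_other(self):
        assert classify_season(SeasonMetrics(), Stratum.MODERATE) == Crop.OTHER

    def test_excluded_stratum_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            classify_season(SeasonMetrics(), Stratum.EXCLUDED)

    def test_labels_stable_over_sigma_sensitivity_band(self):
        """Noise-free fixture labels do not depend on the RCPN stabiliser
        within [0.001, 0.05]."""
        from phenocrop.pipeline import PipelineParams, classify_pixel

        for sigma in (0.001, 0.01, 0.05):
            params = PipelineParams(thresholds=ThresholdConfig(sigma=sigma))
            for code in (14, 15, 16, 17, 246):
                assert classify_pixel(pc.simulate_pixel(code), 1.0, params).code == code


class TestRuleInvariants:
    def _random_metrics(self, n=10_000):
        rng = np.random.default_rng(12)
        return [
            SeasonMetrics(
                lswi_min=rng.uniform(-0.1, 0.4),
                lswi_max=rng.uniform(0.0, 0.5),
                rcle=rng.uniform(0.0, 1.2),
                eve=rng.uniform(0.0, 1.0),
                evl=rng.uniform(0.0, 1.0),
                rcpn=rng.uniform(0.0, 1.0),
            )
            for _ in range(n)
        ]

    def test_threshold_monotonicity(self):
        """Raising theta5 never adds maize labels; lowering theta2 never adds
        rice labels."""
        metrics = self._random_metrics(2000)
        base = ThresholdConfig()
        up5 = ThresholdConfig(theta5=(0.55, 0.45, 0.35))
        down2 = ThresholdConfig(theta2=(0.32, 0.42, 0.52))
        for s in (Stratum.PURE, Stratum.MODERATE, Stratum.SERIOUS):
            maize_base = {i for i, m in enumerate(metrics) if classify_season(m, s, base) == Crop.MAIZE}
            maize_up = {i for i, m in enumerate(metrics) if classify_season(m, s, up5) == Crop.MAIZE}
            assert maize_up <= maize_base
            rice_base = {i for i, m in enumerate(metrics) if classify_season(m, s, base) == Crop.RICE}
            rice_down = {i for i, m in enumerate(metrics) if classify_season(m, s, down2) == Crop.RICE}
            assert rice_down <= rice_base

    def test_stratum_nesting(self):
        """Any season that fires a crop rule under the pure column also fires
        it under the moderate and serious columns (nested thresholds)."""
        thr = DEFAULT_THRESHOLDS
        for m in self._random_metrics(10_000):
            for crop, fires in (
                (Crop.RICE, lambda c: m.lswi_min > c["theta1"] and m.rcle < c["theta2"]),
                (Crop.WHEAT, lambda c: m.eve > c["theta3"] and m.evl > c["theta4"]),
                (Crop.MAIZE, lambda c: m.rcpn > c["theta5"]),
            ):
                cols = [fires(thr.column(s)) for s in (Stratum.PURE, Stratum.MODERATE, Stratum.SERIOUS)]
                if cols[0]:
                    assert cols[1] and cols[2]
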