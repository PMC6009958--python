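"""Sweep planning and trend reporting (full solver sweeps live in the
acceptance suite)."""

import numpy as np
import pytest

from crosslimb.sweep import (SweepPlan, TIERS, trend_report,
                             angle_series_config, position_series_config,
                             ANGLE_LEVELS, POSITION_LEVELS)


class TestSweepPlan:
    def test_default_levels_per_series(self):
        assert SweepPlan(series="angle").levels == ANGLE_LEVELS
        assert SweepPlan(series="position").levels == POSITION_LEVELS

    def test_levels_must_increase(self):
        with pytest.raises(ValueError):
            SweepPlan(series="angle", levels=(60, 30))
        with pytest.raises(ValueError):
            SweepPlan(series="angle", levels=(60,))

    def test_unknown_series_or_tier(self):
        with pytest.raises(ValueError):
            SweepPlan(series="diagonal")
        with pytest.raises(ValueError):
            SweepPlan(series="angle", tier="galactic")

    def test_config_for_level(self):
        plan = SweepPlan(series="position", levels=(0.48, 1.92))
        cfg = plan.config_for(1.92)
        assert cfg.ratio == pytest.approx(1.92, rel=1e-2)
        cfg = SweepPlan(series="angle").config_for(75.0)
        assert cfg.alpha_deg == 75.0
        assert cfg.l_mm == 42.0

    def test_tier_overrides(self):
        plan = SweepPlan(series="angle", tier="smoke",
                         overrides={"n_cycles": 1})
        assert plan.params["n_cycles"] == 1
        assert plan.params["spacing_mm"] == TIERS["smoke"]["spacing_mm"]

    def test_series_configs_match_printed_fixed_parameters(self):
        assert angle_series_config(45.0).cross_length_mm == 42.0
        assert position_series_config(0.72).side_length_mm == 41.0


class TestTrendReport:
    def rows(self, values, levels=(30, 45, 60, 75, 90)):
        return [{"level": lv, "m": v} for lv, v in zip(levels, values)]

    def test_strictly_decreasing_detected(self):
        rep = trend_report(self.rows([5, 4, 3, 2, 1]), "m", "decreasing")
        assert rep.monotonic and rep.direction == "decreasing"
        assert rep.matches_expected
        assert rep.spearman == pytest.approx(-1.0)

    def test_tie_breaks_strict_monotonicity(self):
        rep = trend_report(self.rows([1, 2, 2, 3, 4]), "m", "increasing")
        assert not rep.monotonic
        assert rep.matches_expected is False

    def test_row_order_irrelevant(self):
        rows = self.rows([1, 2, 3, 4, 5])
        shuffled = [rows[3], rows[0], rows[4], rows[2], rows[1]]
        assert trend_report(rows, "m").to_dict() == \
            trend_report(shuffled, "m").to_dict()

    def test_failed_rows_skipped_and_minimum_enforced(self):
        rows = self.rows([1, 2, 3]) + [{"level": 75, "error": "boom"}]
        rep = trend_report(rows, "m")
        assert rep.levels == (30, 45, 60)
        with pytest.raises(ValueError):
            trend_report(rows[:2], "m")

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError):
            trend_report(self.rows([1, 2, 3, 4, 5]), "nope")
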