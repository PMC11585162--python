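"""Value cleaning, event anchoring, hourly gridding, imputation, encoding."""

import numpy as np
import pytest

from edewarn.io import VitalChannel
from edewarn.preprocess import (
    EmptyGridError,
    ImputationStats,
    TabularEncoder,
    VALID_RANGES,
    build_hourly_grid,
    clean_value,
    compute_time_index,
    fit_imputation_stats,
    impute_grid,
)

from conftest import HOUR, make_visit, hourly_visit

HR = VitalChannel.HR


class TestCleanValue:
    @pytest.mark.parametrize("channel,raw,expected", [
        (VitalChannel.BT, "３６.５", 36.5),      # full-width digits
        (VitalChannel.SPO2, "100", 100.0),       # closed upper bound retained
        (VitalChannel.HR, "300", None),          # half-open upper bound
        (VitalChannel.RR, "abc", None),          # non-numeric
        (VitalChannel.SBP, "299.9", 299.9),
        (VitalChannel.SBP, "-1", None),
        (VitalChannel.RR, "50", None),
        (VitalChannel.RR, "49.9", 49.9),
        (VitalChannel.HR, "", None),
        (VitalChannel.BT, " 37.0 ", 37.0),
        (VitalChannel.SPO2, "100.1", None),
    ])
    def test_examples(self, channel, raw, expected):
        assert clean_value(channel, raw) == expected

    def test_unknown_channel_raises(self):
        with pytest.raises(KeyError):
            clean_value("PULSE", "80")


class TestTimeIndex:
    def _cpr_visit(self):
        return make_visit("C", [(0, HR, 80)], cpr=True, cpr_time_s=10 * HOUR)

    def test_event_time_is_zero(self):
        assert compute_time_index(10 * HOUR, self._cpr_visit()) == 0

    def test_ceiling_of_minus_90min_is_minus_one(self):
        assert compute_time_index(10 * HOUR - 5400, self._cpr_visit()) == -1

    def test_ceiling_of_minus_30min_is_zero(self):
        assert compute_time_index(10 * HOUR - 1800, self._cpr_visit()) == 0

    def test_exact_hour_boundary(self):
        assert compute_time_index(9 * HOUR, self._cpr_visit()) == -1

    def test_no_event_anchor_is_last_measurement(self):
        v = make_visit("N", [(HOUR, HR, 80), (5 * HOUR, HR, 82)])
        assert compute_time_index(5 * HOUR, v) == 0
        assert compute_time_index(HOUR, v) == -4

    def test_cpr_without_time_rejected_at_construction(self):
        from edewarn.io import Outcome
        with pytest.raises(ValueError):
            Outcome(cpr=True, dead=False)


class TestHourlyGrid:
    def test_same_bin_latest_wins(self):
        v = make_visit("V", [(4 * HOUR + 600, HR, 90), (4 * HOUR + 1800, HR, 95)])
        g = build_hourly_grid(v)
        i = list(VitalChannel).index(HR)
        assert g.values[i, g.column_index(0)] == 95.0

    def test_triage_panel_occupies_earliest_bin(self):
        v = make_visit("V", [(6 * HOUR, HR, 99)], vitals={HR: "77"})
        g = build_hourly_grid(v)
        i = list(VitalChannel).index(HR)
        assert g.t_min == -6
        assert g.values[i, g.column_index(-6)] == 77.0
        assert g.values[i, g.column_index(0)] == 99.0

    def test_single_hour_visit_gives_length_one(self):
        v = make_visit("V", [(600, HR, 80), (1200, HR, 81)])
        g = build_hourly_grid(v)
        assert g.length == 1

    def test_post_cpr_measurements_dropped(self):
        v = make_visit("V", [(HOUR, HR, 80), (12 * HOUR, HR, 180)],
                       cpr=True, cpr_time_s=10 * HOUR)
        g = build_hourly_grid(v)
        i = list(VitalChannel).index(HR)
        # the T=+2 measurement is gone; last HR cell is the triage carry or T=-9
        assert g.column_index(0) == g.length - 1
        assert not g.observed_mask[i, g.column_index(0)]

    def test_no_valid_measurement_raises(self):
        v = make_visit("V", [(HOUR, HR, "abc")],
                       vitals={c: "nope" for c in VitalChannel})
        with pytest.raises(EmptyGridError):
            build_hourly_grid(v)


class TestImputation:
    def _stats(self):
        return ImputationStats(medians={
            VitalChannel.SBP: 120.0, VitalChannel.DBP: 75.0, VitalChannel.HR: 82.0,
            VitalChannel.SPO2: 97.0, VitalChannel.BT: 36.5, VitalChannel.RR: 16.0})

    def _grid_with_row(self, row):
        v = hourly_visit(n_hours=len(row))
        g = build_hourly_grid(v)
        i = list(VitalChannel).index(HR)
        g.values[:] = np.nan
        g.observed_mask[:] = False
        g.values[i, :] = [np.nan if x is None else x for x in row]
        g.observed_mask[i, :] = [x is not None for x in row]
        return g, i

    def test_carry_forward_with_median_fallback(self):
        g, i = self._grid_with_row([None, 120, None, None, 90])
        out = impute_grid(g, self._stats())
        np.testing.assert_allclose(out.values[i], [82.0, 120, 120, 120, 90])

    def test_observed_cells_and_mask_unchanged(self):
        g, i = self._grid_with_row([70, None, 75, None, None])
        mask_before = g.observed_mask.copy()
        out = impute_grid(g, self._stats())
        np.testing.assert_array_equal(out.observed_mask, mask_before)
        assert out.values[i, 0] == 70 and out.values[i, 2] == 75

    def test_idempotent(self):
        g, _ = self._grid_with_row([None, 120, None, 90, None])
        once = impute_grid(g, self._stats())
        twice = impute_grid(once, self._stats())
        np.testing.assert_array_equal(once.values, twice.values)

    def test_imputed_values_within_validity_intervals(self):
        g, _ = self._grid_with_row([None, 120, None, None, 90])
        out = impute_grid(g, self._stats())
        for i, ch in enumerate(VitalChannel):
            lo, hi, closed = VALID_RANGES[ch]
            row = out.values[i]
            assert np.all(np.isfinite(row))
            assert np.all(row >= lo)
            assert np.all(row <= hi) if closed else np.all(row < hi)


class TestStatsAndEncoding:
    def _visits(self):
        return [
            hourly_visit("A", judgement_code="A", age=30),
            hourly_visit("B", judgement_code="A", age=40),
            hourly_visit("C", judgement_code="B", age=50),
        ]

    def test_mode_majority_and_missing_encodes_as_mode(self):
        visits = self._visits()
        stats = fit_imputation_stats(visits)
        assert stats.modes["judgement_code"] == "A"
        enc = TabularEncoder().fit(visits, stats)
        missing = hourly_visit("D", judgement_code=np.nan)
        vec = enc.encode(missing.triage)
        names = enc.feature_names_
        assert vec[names.index("judgement_code=A")] == 1.0
        assert vec[names.index("judgement_code=B")] == 0.0

    def test_mode_tie_breaks_alphabetically(self):
        visits = [hourly_visit("A", judgement_code="B"),
                  hourly_visit("B", judgement_code="A")]
        stats = fit_imputation_stats(visits)
        assert stats.modes["judgement_code"] == "A"

    def test_numeric_passthrough_unscaled(self):
        visits = self._visits()
        enc = TabularEncoder().fit(visits)
        vec = enc.encode(visits[0].triage)
        assert vec[enc.feature_names_.index("age")] == 30.0

    def test_one_hot_blocks_sum_to_one_and_length_fixed(self):
        visits = self._visits()
        enc = TabularEncoder().fit(visits)
        from edewarn.io import TRIAGE_FEATURES
        lengths = set()
        for v in visits + [hourly_visit("E", judgement_code="ZZZ")]:
            vec = enc.encode(v.triage)
            lengths.add(len(vec))
            pos = 0
            for feat, kind in TRIAGE_FEATURES.items():
                if kind == "numeric":
                    pos += 1
                    continue
                block = vec[pos:pos + len(enc.categories_[feat])]
                assert block.sum() == 1.0
                pos += len(block)
        assert len(lengths) == 1

    def test_stats_text_roundtrip_bit_identical(self):
        visits = self._visits()
        stats = fit_imputation_stats(visits)
        back = ImputationStats.from_text(stats.to_text())
        assert back.medians == stats.medians
        assert back.modes == stats.modes
        assert back.numeric_mean == stats.numeric_mean

    def test_median_fitted_on_training_only(self):
        train = [hourly_visit("A", value=60), hourly_visit("B", value=70)]
        stats = fit_imputation_stats(train)
        # triage HR (80) enters the pool too: values {60,60,60,60,70,70,70,70,80,80}
        assert stats.medians[HR] == pytest.approx(np.median([60] * 4 + [70] * 4 + [80, 80]))
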