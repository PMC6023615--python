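"""Gating, classification, mode detection, and summary tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from redoxcyto import (
    AgingSimConfig,
    RedoxGates,
    aging_timecourse,
    classify_redox,
    crosstab_marker_redox,
    fit_calibration,
    gate_live,
    gate_probe_positive,
    gen_aging_culture,
    gen_calibration_controls,
    ratio_distribution,
    summarize_population,
)
from redoxcyto.cytometry import MissingChannelError, SubpopulationSummary

from conftest import make_events


class TestGates:
    def test_live_gate_keeps_all_when_dye_dark(self, gates):
        ev = make_events([10, 20], [10, 20], pi=[0, 0])
        out = gate_live(ev, gates)
        assert len(out) == 2 and out.attrs["n_excluded_dead"] == 0

    def test_live_gate_can_empty_the_table_with_warning(self, gates):
        ev = make_events([10, 20], [10, 20], pi=[5000, 9000])
        with pytest.warns(UserWarning):
            out = gate_live(ev, gates)
        assert len(out) == 0 and out.attrs["n_excluded_dead"] == 2

    def test_live_gate_removes_configured_dead_fraction(self, gates):
        cfg = AgingSimConfig(seed=9, dead_base=0.2, dead_rate_per_h=0.0)
        ev = gen_aging_culture(cfg, 0.0, 100_000)
        out = gate_live(ev, gates)
        removed = out.attrs["n_excluded_dead"] / len(ev)
        assert removed == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / 100_000) + 0.003)

    def test_missing_pi_channel_error_names_channel(self, gates):
        ev = pd.DataFrame({"i405": [1.0], "i488": [1.0]})
        with pytest.raises(MissingChannelError, match="pi"):
            gate_live(ev, gates)

    def test_probe_gate_identity_at_zero_floor(self):
        g = RedoxGates(gfp_min=0.0)
        ev = make_events([1, 2, 3], [1, 2, 3])
        assert len(gate_probe_positive(ev, g)) == 3

    def test_probe_gate_requires_both_channels_above_floor(self, gates):
        ev = make_events([1.0, 100.0, 100.0], [100.0, 1.0, 100.0])
        out = gate_probe_positive(ev, gates)
        assert len(out) == 1
        assert out.attrs["n_excluded_probe_negative"] == 2

    def test_probe_gate_removes_configured_negative_fraction(self, gates):
        cfg = AgingSimConfig(
            seed=10, probe_neg_base=0.1, probe_neg_rate_per_h=0.0,
            dead_base=0.0, dead_rate_per_h=0.0,
        )
        ev = gen_aging_culture(cfg, 0.0, 50_000)
        out = gate_probe_positive(ev, RedoxGates())
        removed = out.attrs["n_excluded_probe_negative"] / len(ev)
        # floor-crossing tails move the realized fraction slightly off 0.1
        assert removed == pytest.approx(0.1, abs=0.03)

    def test_gate_order_does_not_change_surviving_labels(self, sim_cfg, gates):
        ev = gen_aging_culture(sim_cfg, 72, 5000)
        ab = gate_probe_positive(gate_live(ev, gates), gates)
        ba = gate_live(gate_probe_positive(ev, gates), gates)
        assert sorted(ab.index) == sorted(ba.index)
        pd.testing.assert_series_equal(
            classify_redox(ab.sort_index(), gates), classify_redox(ba.sort_index(), gates)
        )


class TestClassify:
    def test_band_boundaries(self, gates):
        ev = make_events([0.5, 5.0, 2.0], [1.0, 1.0, 1.0])
        labels = classify_redox(ev, gates)
        assert list(labels) == ["reduced", "oxidized", "intermediate"]

    def test_zero_488_flagged_undefined(self, gates):
        ev = make_events([1.0, 1.0], [0.0, 1.0])
        labels = classify_redox(ev, gates)
        assert labels.iloc[0] == "undefined"

    @given(c=st.floats(1e-3, 1e3))
    def test_scale_invariance_of_labels(self, gates, c):
        ev = make_events([0.5, 5.0, 2.0], [1.0, 1.0, 1.0])
        scaled = make_events(np.array([0.5, 5.0, 2.0]) * c, np.array([1.0, 1.0, 1.0]) * c)
        pd.testing.assert_series_equal(classify_redox(ev, gates), classify_redox(scaled, gates))

    def test_misclassification_below_two_percent_on_default_culture(self, sim_cfg, gates):
        ev = gen_aging_culture(sim_cfg, 96, 10_000)
        live = ev[ev["truth_state"].isin(["reduced", "oxidized", "intermediate"])]
        labels = classify_redox(live, gates)
        mismatch = (labels != live["truth_state"]).mean()
        assert mismatch < 0.02


class TestRatioDistribution:
    def test_single_population_has_one_mode_near_its_slope(self, sim_cfg):
        red, _ = gen_calibration_controls(sim_cfg, 5000)
        dens = ratio_distribution(red)
        assert dens.n_modes == 1
        assert dens.mode_locations[0] == pytest.approx(sim_cfg.slope_red, abs=0.1)

    def test_single_mode_is_stable_across_seeds(self):
        for seed in range(5):
            red, _ = gen_calibration_controls(AgingSimConfig(seed=seed), 3000)
            assert ratio_distribution(red).n_modes == 1

    def test_two_gaussian_mixture_modes_recovered(self, rng):
        ratios = np.concatenate(
            [rng.normal(0.6, 0.1, 5000), rng.normal(6.0, 0.4, 5000)]
        )
        dens = ratio_distribution(ratios)
        assert dens.n_modes == 2
        lo, hi = sorted(dens.mode_locations)
        assert lo == pytest.approx(0.6, abs=0.1)
        assert hi == pytest.approx(6.0, abs=0.1)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            ratio_distribution(np.ones(50))


class TestSummarize:
    def test_all_reduced_input_summarizes_to_pure_reduced(self, sim_cfg, gates):
        cfg = AgingSimConfig(
            seed=11, ox_frac_max=0.0, dead_base=0.0, dead_rate_per_h=0.0,
            probe_neg_base=0.0, probe_neg_rate_per_h=0.0, frac_intermediate=0.0,
        )
        red, ox = gen_calibration_controls(sim_cfg, 2000)
        cal = fit_calibration(red, ox)
        s = summarize_population(gen_aging_culture(cfg, 24, 2000), cal, gates)
        assert s.frac_reduced > 0.99
        assert s.frac_oxidized == pytest.approx(0.0, abs=0.005)

    def test_fraction_sum_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            SubpopulationSummary(
                age_h=24, n_total=10, n_live=10, n_probe_pos=10,
                frac_reduced=0.7, frac_oxidized=0.5, frac_intermediate=0.0,
                mode_locations=(), mean_oxd=0.0,
            )

    def test_oxidized_fraction_tracks_generator_truth(self, sim_cfg, gates):
        red, ox = gen_calibration_controls(sim_cfg, 5000)
        cal = fit_calibration(red, ox)
        ev = gen_aging_culture(sim_cfg, 72, 10_000, seed=77)
        s = summarize_population(ev, cal, gates)
        live = ev[ev["truth_state"].isin(["reduced", "oxidized", "intermediate"])]
        truth = (live["truth_state"] == "oxidized").mean()
        assert abs(s.frac_oxidized - truth) < 0.02


class TestTimecourse:
    def _summary(self, age, frac_ox):
        return SubpopulationSummary(
            age_h=age, n_total=100, n_live=100, n_probe_pos=100,
            frac_reduced=1 - frac_ox, frac_oxidized=frac_ox, frac_intermediate=0.0,
            mode_locations=(0.6,), mean_oxd=frac_ox,
        )

    def test_constant_fractions_give_zero_increments(self):
        tc = aging_timecourse([self._summary(a, 0.3) for a in (24, 48, 72)])
        assert tc["frac_oxidized_increment"].iloc[1:].eq(0).all()

    def test_two_age_increment_is_plain_difference(self):
        tc = aging_timecourse([self._summary(24, 0.1), self._summary(48, 0.35)])
        assert tc["frac_oxidized_increment"].iloc[1] == pytest.approx(0.25)
        assert tc["largest_increment"].iloc[1]

    def test_rows_sorted_by_age(self):
        tc = aging_timecourse([self._summary(72, 0.4), self._summary(24, 0.1)])
        assert list(tc["age_h"]) == [24.0, 72.0]

    def test_duplicate_ages_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            aging_timecourse([self._summary(24, 0.1), self._summary(24, 0.2)])


class TestCrosstab:
    def test_missing_marker_channel_rejected(self, gates):
        ev = make_events([1.0], [1.0])
        with pytest.raises(MissingChannelError, match="marker"):
            crosstab_marker_redox(ev, gates, threshold=10.0)

    def test_all_low_marker_yields_single_row(self, gates):
        ev = make_events([60.0] * 200, [100.0] * 200, marker=[0.0] * 200)
        tab = crosstab_marker_redox(ev, gates, threshold=10.0)
        assert list(tab.index) == ["marker_low"]

    def test_row_fractions_sum_to_at_most_one(self, sim_cfg, gates):
        ev = gen_aging_culture(sim_cfg, 72, 10_000)
        tab = crosstab_marker_redox(ev, gates, threshold=800.0)
        sums = tab[["frac_reduced", "frac_oxidized", "frac_intermediate"]].sum(axis=1)
        assert (sums <= 1 + 1e-9).all()

    def test_marker_high_oxidized_enrichment_recovered(self, gates, rng):
        # construct events where marker-high cells are 90% oxidized
        n = 20_000
        high = rng.random(n) < 0.5
        oxidized = np.where(high, rng.random(n) < 0.9, rng.random(n) < 0.1)
        ratio = np.where(oxidized, 7.0, 0.6)
        i488 = rng.lognormal(np.log(100), 0.3, n)
        ev = make_events(ratio * i488, i488, marker=np.where(high, 3000.0, 100.0))
        tab = crosstab_marker_redox(ev, gates, threshold=1000.0)
        se = 3 * np.sqrt(0.9 * 0.1 / (n / 2))
        assert tab.loc["marker_high", "frac_oxidized"] == pytest.approx(0.9, abs=se)
        assert tab.loc["marker_low", "frac_oxidized"] == pytest.approx(0.1, abs=se)

    def test_quantile_split_mode(self, sim_cfg, gates):
        ev = gen_aging_culture(sim_cfg, 72, 5000)
        tab = crosstab_marker_redox(ev, gates, quantile=0.5)
        assert set(tab.index) == {"marker_high", "marker_low"}
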