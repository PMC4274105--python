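import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from pollenbeetle.insecticide import (
    Compound,
    ControlStrategy,
    LAMBDA_CYHALOTHRIN,
    PYMETROZINE,
    STRATEGY_PRESETS,
    decide_treatment,
    dose_over_step,
    efficacy_at,
    genotype_susceptibility,
    kill_probability_step,
)

LC = LAMBDA_CYHALOTHRIN


class TestEfficacy:
    def test_maximum_at_application(self):
        assert efficacy_at(0.0, 0.0, LC) == 1.0

    def test_zero_at_end_of_decline(self):
        assert efficacy_at(LC.d_max + LC.d_decl, 0.0, LC) == pytest.approx(
            0.0, abs=1e-12
        )
        assert efficacy_at(LC.d_max + LC.d_decl + 0.1, 0.0, LC) == 0.0

    def test_half_at_midpoint_of_decline(self):
        assert efficacy_at(LC.d_max + LC.d_decl / 2, 0.0, LC) == pytest.approx(0.5)

    def test_zero_before_application(self):
        assert efficacy_at(3.0, 5.0, LC) == 0.0

    def test_plateau_then_linear(self):
        t = np.linspace(0, LC.d_max, 20)
        assert np.allclose(efficacy_at(t, 0.0, LC), 1.0)


class TestDose:
    def test_unit_dose_inside_plateau(self):
        assert dose_over_step(1.0, 2.0, [(0.0, LC)]) == pytest.approx(1.0)

    def test_whole_curve_area(self):
        # rectangle + triangle: 4.7 + 6/2 = 7.7
        assert dose_over_step(0.0, 50.0, [(0.0, LC)]) == pytest.approx(7.7)

    def test_no_active_treatment(self):
        assert dose_over_step(0.0, 1.0, []) == 0.0

    def test_two_overlapping_treatments_sum(self):
        d = dose_over_step(0.0, 1.0, [(0.0, LC), (0.0, LC)])
        assert d == pytest.approx(2.0)

    def test_pymetrozine_whole_curve(self):
        assert dose_over_step(0.0, 50.0, [(0.0, PYMETROZINE)]) == pytest.approx(
            1.5 + 10.6 / 2
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.floats(-2.0, 14.0),
        st.floats(0.01, 14.0),
        st.floats(0.0, 3.0),
    )
    def test_matches_numerical_quadrature(self, t0, width, ta):
        t1 = t0 + width
        expected, _ = quad(
            lambda t: efficacy_at(t, ta, LC), t0, t1, limit=200,
            points=[ta, ta + LC.d_max, ta + LC.d_max + LC.d_decl],
        )
        assert dose_over_step(t0, t1, [(ta, LC)]) == pytest.approx(
            expected, abs=1e-9
        )


class TestSusceptibility:
    def test_recessive_heterozygote_equals_susceptible(self):
        c = Compound("x", 4.7, 6.0, 0.86, 0.003, 0.0)
        s = genotype_susceptibility(c)
        assert s[1] == pytest.approx(s[0])

    def test_intermediate_is_arithmetic_mean(self):
        c = Compound("x", 4.7, 6.0, 0.86, 0.003, 1.0)
        assert genotype_susceptibility(c)[1] == pytest.approx(0.4315)

    def test_calibrated_dominant_value(self):
        # (48.6 * 0.003 + 0.86) / 49.6
        assert genotype_susceptibility(LC)[1] == pytest.approx(0.0202782, abs=1e-6)

    def test_interpolates_between_homozygotes_monotone_in_w(self):
        ws = np.linspace(0, 1000, 60)
        vals = [
            genotype_susceptibility(Compound("x", 1, 1, 0.86, 0.003, w))[1]
            for w in ws
        ]
        assert vals[0] == pytest.approx(0.86)
        assert vals[-1] == pytest.approx(0.003, abs=0.02)
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestKillProbability:
    def test_zero_susceptibility_zero_kill(self):
        p, dmg = kill_probability_step(0.0, 5.0, 1.0)
        assert p == 0.0 and dmg == 1.0

    def test_one_full_day_at_max_efficacy(self):
        p, dmg = kill_probability_step(0.86, 1.0, 0.0)
        assert p == pytest.approx(1 - np.exp(-0.86))
        assert dmg == pytest.approx(0.86)

    def test_cumulative_kill_over_whole_curve(self):
        # hazard additivity: any partition compounds to 1 - exp(-S * 7.7)
        total_dose = 7.7
        surv = 1.0
        for lo, hi in [(0, 2), (2, 3.3), (3.3, 8.0), (8.0, 20.0)]:
            dose = dose_over_step(lo, hi, [(0.0, LC)])
            p, _ = kill_probability_step(0.86, dose)
            surv *= 1 - p
        assert 1 - surv == pytest.approx(1 - np.exp(-0.86 * total_dose), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 5.0), min_size=1, max_size=8))
    def test_step_partition_invariance(self, widths):
        # survival depends only on total exposure, not on how it is split
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        surv = 1.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            dose = dose_over_step(lo, hi, [(0.0, LC)])
            p, _ = kill_probability_step(0.5, dose)
            surv *= 1 - p
        total = dose_over_step(0.0, edges[-1], [(0.0, LC)])
        p_total, _ = kill_probability_step(0.5, total)
        assert surv == pytest.approx(1 - p_total, abs=1e-12)

    def test_monotone_in_dose_and_susceptibility(self):
        doses = np.linspace(0, 8, 30)
        p = kill_probability_step(0.5, doses)[0]
        assert np.all(np.diff(p) > 0)
        ss = np.linspace(0, 1, 30)
        p2 = np.array([kill_probability_step(s, 3.0)[0] for s in ss])
        assert np.all(np.diff(p2) > 0)


class TestDecisions:
    def test_calendar_single_treatment_10_days_after_onset(self):
        strat = STRATEGY_PRESETS["C1"]
        fired = [
            day
            for day in range(120, 160)
            if decide_treatment(
                strat, crop="WOSR", day=day, flowering_onset_day=120,
                adult_density=0.0, season_treatment_days=[], compound=LC,
            )
        ]
        assert fired == [130]

    def test_threshold_below_does_not_fire(self):
        strat = STRATEGY_PRESETS["HT"]
        assert not decide_treatment(
            strat, crop="WOSR", day=140, flowering_onset_day=120,
            adult_density=14.9, season_treatment_days=[], compound=LC,
        )

    def test_threshold_at_or_above_fires(self):
        strat = STRATEGY_PRESETS["HT"]
        assert decide_treatment(
            strat, crop="WOSR", day=140, flowering_onset_day=120,
            adult_density=15.0, season_treatment_days=[], compound=LC,
        )
        assert decide_treatment(
            strat, crop="SOSR", day=140, flowering_onset_day=120,
            adult_density=5.0, season_treatment_days=[], compound=LC,
        )

    def test_two_per_season_cap(self):
        for name in ("C2", "HT", "LT"):
            strat = STRATEGY_PRESETS[name]
            assert not decide_treatment(
                strat, crop="WOSR", day=140, flowering_onset_day=120,
                adult_density=99.0, season_treatment_days=[125, 136], compound=LC,
            )

    def test_retreat_interval_blocks_back_to_back_sprays(self):
        strat = STRATEGY_PRESETS["LT"]
        assert not decide_treatment(
            strat, crop="WOSR", day=135, flowering_onset_day=120,
            adult_density=50.0, season_treatment_days=[130], compound=LC,
        )
        # after Dmax + Ddecl = 10.7 days the field may be re-treated
        assert decide_treatment(
            strat, crop="WOSR", day=141, flowering_onset_day=120,
            adult_density=50.0, season_treatment_days=[130], compound=LC,
        )

    def test_invalid_strategy_parameters_rejected(self):
        with pytest.raises(ValueError):
            ControlStrategy("bad", "weekly")
        with pytest.raises(ValueError):
            ControlStrategy("bad", "calendar", calendar_offsets=(0,))
        with pytest.raises(ValueError):
            ControlStrategy("bad", "threshold", thresholds={"WOSR": -5})
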