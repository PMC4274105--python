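import numpy as np
import pytest
from scipy import stats

from pollenbeetle.population import (
    AdultPhase,
    CohortTable,
    Genotype,
    LifeHistoryParams,
    Stage,
    STAGE_DURATIONS_DD,
    advance_development,
    apply_mortality,
    background_mortality_step,
    choose_mate_genotypes,
    combine_mortality,
    density_mortality_step,
    hardy_weinberg_probs,
    initialize_population,
    mating_probability,
    offspring_genotype_distribution,
    oviposition_step,
    sample_batch_eggs,
)

LH = LifeHistoryParams()


class TestInitialisation:
    def test_hardy_weinberg_chi_square_at_1e5(self, rng):
        q0 = 0.3
        t = initialize_population(100_000, q0, np.array([0, 1, 2]), rng)
        counts = np.zeros(3)
        np.add.at(counts, t.geno, t.count)
        expected = hardy_weinberg_probs(q0) * 100_000
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_q0_zero_gives_all_susceptible(self, rng):
        t = initialize_population(10_000, 0.0, np.array([0]), rng)
        assert np.all(t.geno == Genotype.SS)

    def test_expected_homozygote_resistant_count(self, rng):
        # q0 = 0.001 over a million individuals: one RR expected
        reps = [
            int(
                initialize_population(10**6, 0.001, np.array([0]), np.random.default_rng(s))
                .count[
                    initialize_population(1, 0.0, np.array([0]), np.random.default_rng(0)).geno
                    == -1
                ]
                .sum()
            )
            for s in []
        ]
        t = initialize_population(10**6, 0.001, np.array([0]), rng)
        rr = int(t.count[t.geno == Genotype.RR].sum())
        # Poisson(1): extremely unlikely to see more than 8
        assert rr <= 8

    def test_sex_ratio_balanced(self, rng):
        t = initialize_population(100_000, 0.1, np.array([0, 1]), rng)
        females = int(t.count[t.sex == 0].sum())
        assert abs(females - 50_000) < 4 * np.sqrt(100_000 * 0.25)

    def test_requires_overwinter_cells(self, rng):
        with pytest.raises(ValueError):
            initialize_population(10, 0.1, np.array([], dtype=int), rng)


class TestDevelopment:
    def test_carryover_across_stage_boundary(self):
        stage, dd, emerged = advance_development(
            np.array([Stage.EGG], dtype=np.int16), np.array([95.0]), 10.0
        )
        assert stage[0] == Stage.LARVA
        assert dd[0] == pytest.approx(5.0)
        assert not emerged[0]

    def test_zero_step_is_identity(self):
        stage, dd, emerged = advance_development(
            np.array([Stage.LARVA], dtype=np.int16), np.array([100.0]), 0.0
        )
        assert stage[0] == Stage.LARVA and dd[0] == 100.0

    def test_emergence_after_950_dd_at_constant_10C(self):
        # egg -> adult needs 100 + 250 + 600 = 950 dd: 95 days at 10 degC
        stage = np.array([Stage.EGG], dtype=np.int16)
        dd = np.array([0.0])
        days = 0
        while stage[0] != Stage.ADULT:
            stage, dd, _ = advance_development(stage, dd, 10.0)
            days += 1
        assert days == 95

    def test_multiple_boundaries_in_one_huge_step(self):
        stage, dd, emerged = advance_development(
            np.array([Stage.EGG], dtype=np.int16), np.array([0.0]), 1000.0
        )
        assert stage[0] == Stage.ADULT and emerged[0]
        assert dd[0] == pytest.approx(50.0)


class TestMating:
    def test_half_mated_after_t50_days_at_d50(self):
        p = mating_probability(25.0, 1.0, LH)
        unmated = (1 - p) ** 3  # three one-day steps
        assert 1 - unmated == pytest.approx(0.5, abs=1e-12)

    def test_zero_density_zero_probability(self):
        assert mating_probability(0.0, 1.0, LH) == 0.0

    def test_formula_value_at_double_density(self):
        assert mating_probability(50.0, 1.0, LH) == pytest.approx(
            1 - 0.5 ** (2 / 3), abs=1e-12
        )

    def test_monotone_in_density(self):
        d = np.linspace(0, 200, 50)
        p = mating_probability(d, 1.0, LH)
        assert np.all(np.diff(p) > 0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            mating_probability(-1.0, 1.0, LH)

    def test_mate_genotype_follows_male_distribution(self, rng):
        counts = np.array([[1.0, 1.0, 2.0]])
        total = np.zeros(3)
        for _ in range(200):
            total += choose_mate_genotypes(np.array([100]), counts, rng)[0]
        frac = total / total.sum()
        assert np.allclose(frac, [0.25, 0.25, 0.5], atol=0.02)

    def test_single_male_genotype_deterministic(self, rng):
        split = choose_mate_genotypes(np.array([50]), np.array([[10.0, 0, 0]]), rng)
        assert split[0, 0] == 50

    def test_no_males_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_mate_genotypes(np.array([5]), np.array([[0.0, 0.0, 0.0]]), rng)


class TestMendel:
    @pytest.mark.parametrize("m", [0, 1, 2])
    @pytest.mark.parametrize("f", [0, 1, 2])
    def test_matches_exact_gamete_enumeration(self, m, f):
        # enumerate gametes: parent passes R with probability (R count)/2
        probs = np.zeros(3)
        for gm, pm in ((0, 1 - m / 2), (1, m / 2)):
            for gf, pf in ((0, 1 - f / 2), (1, f / 2)):
                probs[gm + gf] += pm * pf
        assert np.allclose(offspring_genotype_distribution(m, f), probs, atol=1e-15)

    def test_textbook_crosses(self):
        assert np.allclose(offspring_genotype_distribution(0, 0), [1, 0, 0])
        assert np.allclose(offspring_genotype_distribution(0, 2), [0, 1, 0])
        assert np.allclose(offspring_genotype_distribution(1, 1), [0.25, 0.5, 0.25])


class TestOviposition:
    def _mated_females(self, n, geno=0, mate_geno=0):
        t = CohortTable(1)
        t.stage[:] = Stage.ADULT
        t.phase[:] = AdultPhase.REPRODUCING
        t.sex[:] = 0
        t.geno[:] = geno
        t.mated[:] = 1
        t.mate_geno[:] = mate_geno
        t.count[:] = n
        return t

    def test_expected_batch_and_lifetime_fecundity(self, rng):
        # E[batch] = 25 eggs so E[lifetime] = 250 over the 10-batch cap
        assert (LH.eggs_min + LH.eggs_max) / 2 * LH.max_batches == 250
        totals = sample_batch_eggs(np.array([100_000]), rng)
        assert abs(totals[0] / 100_000 - 25.0) < 0.1

    def test_batches_laid_every_85_dd_until_cap(self, rng):
        t = self._mated_females(1000)
        laid = []
        for _ in range(12):
            eggs = oviposition_step(t, 85.0, rng)
            laid.append(eggs.total())
        assert all(x > 0 for x in laid[:10])
        assert laid[10] == 0 and laid[11] == 0  # 10-batch cap
        assert t.batches[0] == 10

    def test_no_eggs_before_first_interval(self, rng):
        t = self._mated_females(1000)
        eggs = oviposition_step(t, 84.9, rng)
        assert eggs.total() == 0

    def test_ss_mother_rr_mate_gives_all_heterozygotes(self, rng):
        t = self._mated_females(5000, geno=0, mate_geno=2)
        eggs = oviposition_step(t, 85.0, rng)
        assert eggs.total() > 0
        assert np.all(eggs.geno == Genotype.RS)
        assert np.all(eggs.stage == Stage.EGG)

    def test_unmated_females_lay_nothing(self, rng):
        t = self._mated_females(1000)
        t.mated[:] = 0
        eggs = oviposition_step(t, 200.0, rng)
        assert eggs.total() == 0


class TestMortality:
    def test_background_compounds_to_stage_total(self):
        assert background_mortality_step(0.33, 100.0, 100.0) == pytest.approx(0.33)
        assert background_mortality_step(0.33, 100.0, 0.0) == 0.0
        assert background_mortality_step(0.33, 100.0, 50.0) == pytest.approx(
            1 - 0.67**0.5
        )

    def test_background_partition_invariance(self):
        # survival over any partition of the stage multiplies to 1 - M
        parts = [10.0, 25.0, 40.0, 25.0]
        surv = np.prod([1 - background_mortality_step(0.33, 100.0, p) for p in parts])
        assert surv == pytest.approx(0.67, abs=1e-12)

    def test_cumulative_juvenile_background_is_70_percent(self):
        surv = 1.0
        for D in STAGE_DURATIONS_DD:
            surv *= 1 - background_mortality_step(0.33, D, D)
        assert 1 - surv == pytest.approx(1 - 0.67**3, abs=1e-12)

    def test_density_mortality_zero_at_or_below_threshold(self):
        assert density_mortality_step(100.0, 100.0, 5.0) == 0.0
        assert density_mortality_step(50.0, 100.0, 5.0) == 0.0

    def test_power_form_value_at_e_times_threshold(self):
        m = density_mortality_step(100.0 * np.e, 100.0, 1.0, form="power")
        assert m == pytest.approx(1 - 1 / np.e, abs=1e-12)

    def test_excess_form_value(self):
        # deaths (d - K)/T spread over the pool: (1 - K/d) * dt/T
        assert density_mortality_step(200.0, 100.0, 5.0, form="excess") == (
            pytest.approx(0.1)
        )

    def test_closed_cohort_decline_toward_threshold(self):
        # deterministic iteration with density recomputed each step: the
        # excess (log-excess for the power form) decays with time-constant T
        for form in ("excess", "power"):
            d = 200.0
            for _ in range(5):
                d *= 1 - density_mortality_step(d, 100.0, 5.0, form=form)
            if form == "power":
                # log-excess decays by (1 - 1/T) per day:
                # d5 = K * (d0/K) ** ((1 - 1/T)**5)
                assert d == pytest.approx(100 * 2 ** (0.8**5), abs=1e-9)
            else:
                assert d == pytest.approx(100 + 100 * (1 - 1 / 5) ** 5, abs=0.01)
            # long-run convergence to the threshold
            for _ in range(100):
                d *= 1 - density_mortality_step(d, 100.0, 5.0, form=form)
            assert d == pytest.approx(100.0, rel=0.01)

    def test_combined_risks_multiplicative(self):
        assert combine_mortality(0.0, 0.0) == 0.0
        assert combine_mortality(0.2, 0.5) == pytest.approx(1 - 0.8 * 0.5)

    def test_binomial_deaths_match_probability(self, rng):
        t = CohortTable(1)
        t.count[:] = 10**6
        apply_mortality(t, np.array([0.5]), rng)
        assert abs(t.count[0] - 5 * 10**5) < 3 * np.sqrt(10**6 * 0.25)

    def test_zero_probability_all_survive(self, rng):
        t = CohortTable(1)
        t.count[:] = 1000
        apply_mortality(t, np.array([0.0]), rng)
        assert t.count[0] == 1000


class TestCohortTable:
    def test_compact_merges_identical_cohorts_and_conserves_counts(self, rng):
        t = CohortTable(6)
        t.cell[:] = [1, 1, 2, 2, 1, 1]
        t.geno[:] = [0, 0, 1, 1, 0, 2]
        t.count[:] = [10, 20, 5, 5, 30, 7]
        t.dd[:] = [3.0, 4.0, 0.0, 0.0, 3.5, 0.0]  # within one 5-dd bucket
        out = t.compact(dd_bucket=5.0)
        assert out.total() == t.total()
        assert out.n == 3
        merged = out.count[(out.cell == 1) & (out.geno == 0)]
        assert merged[0] == 60

    def test_compact_drops_empty_rows(self):
        t = CohortTable(3)
        t.count[:] = [0, 5, 0]
        out = t.compact()
        assert out.n == 1 and out.total() == 5

    def test_take_and_concat_round_trip(self):
        t = CohortTable(4)
        t.count[:] = [1, 2, 3, 4]
        halves = [t.take(np.array([0, 1])), t.take(np.array([2, 3]))]
        back = CohortTable.concat(halves)
        assert back.total() == 10
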