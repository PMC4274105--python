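"""Daily scheduler composing weather, crops, demography, dispersal and
insecticide treatments; outbreak detection; Monte Carlo scenario harness.

A simulation starts on 1 July of a spin-up half-year with the initial adult
population hibernating in the overwintering cells, so the first winter
oilseed-rape crop is sown inside the simulated window.  Each day advances
through a fixed sub-step order: (1) weather and degree-days, (2) sowing and
crop phenology, (3) seasonal transitions, (4) treatment decisions, (5)
insecticide mortality, (6) natural mortality, (7) development, (8) mating
and oviposition, (9) movement (instantaneous, at the end of the step).
Treatment decisions therefore see pre-mortality densities, and movement
cannot cascade within a day.

A *resistance outbreak* is the first day starting an uninterrupted run of at
least 183 days (six months) with the R-allele frequency above 50%, reported
in years since simulation start (day / 365.25).  The frequency is computed
over all living individuals of all stages.

The Monte Carlo harness reproduces the scenario experiment design: for each
management scenario, one run per combination of independently seeded
landscape arrangements and weather series (6 x 6 = 36 by default), each run
reproducible from three separate seed streams (landscape, weather,
demography).  At desk scale a population scaling factor (default 1e-3) maps
the field-scale initial population of 1e9 insects to tractable counts while
leaving all per-plant and per-m^2 densities unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import weather as wx
from . import landscape as ls
from .dispersal import MovementParams, destination_matrix, execute_movements
from .insecticide import (
    Compound,
    ControlStrategy,
    LAMBDA_CYHALOTHRIN,
    STRATEGY_PRESETS,
    dose_over_step,
    genotype_susceptibility,
)
from .population import (
    AdultPhase,
    CohortTable,
    LifeHistoryParams,
    MortalityParams,
    STAGE_DURATIONS_DD,
    Stage,
    advance_development,
    allele_frequency_of,
    apply_mortality,
    background_mortality_step,
    choose_mate_genotypes,
    combine_mortality,
    density_mortality_step,
    initialize_population,
    mating_probability,
    oviposition_step,
)

DAYS_PER_YEAR_MEAN = 365.25


@dataclass
class SimulationConfig:
    """Full configuration of a single landscape simulation."""

    years: int = 50
    scale: float = 1e-3
    initial_population: float = 1e9
    initial_r_freq: float = 0.001
    p_sosr: float = 0.05
    strategy: Optional[str | ControlStrategy] = "HT"
    compound: Compound = LAMBDA_CYHALOTHRIN
    dominance_w: Optional[float] = None  # overrides compound.w when set
    site: str | wx.SiteClimate = "rothamsted-like"
    dims: tuple = (10, 10)
    composition: Optional[dict] = None
    landscape_seed: int = 0
    weather_seed: int = 1
    demography_seed: int = 2
    outbreak_threshold: float = 0.5
    outbreak_persistence_days: int = 183
    dd_bucket: float = 5.0
    stop_at_outbreak: bool = False
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    movement: MovementParams = field(default_factory=MovementParams)
    phenology: ls.CropPhenologyParams = field(default_factory=ls.CropPhenologyParams)

    def resolved_strategy(self) -> Optional[ControlStrategy]:
        if self.strategy is None:
            return None
        if isinstance(self.strategy, ControlStrategy):
            return self.strategy
        return STRATEGY_PRESETS[self.strategy]

    def resolved_compound(self) -> Compound:
        c = self.compound
        return c if self.dominance_w is None else c.with_dominance(self.dominance_w)

    def resolved_site(self) -> wx.SiteClimate:
        if isinstance(self.site, wx.SiteClimate):
            return self.site
        return wx.SITE_PRESETS[self.site]

    def validate(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if not 0 <= self.initial_r_freq <= 1:
            raise ValueError("initial_r_freq must be in [0, 1]")
        if not 0 <= self.p_sosr <= 1:
            raise ValueError("p_sosr must be in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class OutbreakResult:
    """Trajectories and outbreak summary of one simulation run."""

    q: np.ndarray                    # daily R-allele frequency (nan if empty)
    stage_counts: np.ndarray         # (n_days, 4) counts by stage
    treatments: list                 # (day, cell, compound, trigger)
    outbreak_day: Optional[int]
    eggs_laid_by_year: np.ndarray
    adults_emerged_by_year: np.ndarray
    eggs_laid_by_cell_year: np.ndarray
    adults_emerged_by_cell_year: np.ndarray
    old_age_deaths: int
    config: SimulationConfig

    def old_age_fraction(self) -> float:
        """Fraction of all insects born that die of old age (complete the
        full life cycle) rather than of predation, competition or season's
        end."""
        born = int(self.eggs_laid_by_year.sum())
        return self.old_age_deaths / born if born else float("nan")

    @property
    def n_days(self) -> int:
        return self.q.size

    @property
    def outbreak_year(self) -> Optional[float]:
        if self.outbreak_day is None:
            return None
        return self.outbreak_day / DAYS_PER_YEAR_MEAN

    @property
    def final_q(self) -> float:
        valid = self.q[~np.isnan(self.q)]
        return float(valid[-1]) if valid.size else float("nan")

    def juvenile_mortality_by_year(self, burn_in_years: int = 5) -> np.ndarray:
        """Per-year fraction dying between egg laying and end of pupal stage.

        Cohorts laid in a calendar year emerge (or die) the same year, so the
        yearly ratio of adult emergences to eggs laid measures the overall
        birth-to-pupation mortality.  Years within the burn-in and years
        without eggs are excluded.
        """
        laid = self.eggs_laid_by_year
        emerged = self.adults_emerged_by_year
        ok = (np.arange(laid.size) > burn_in_years) & (laid > 0)
        return 1.0 - emerged[ok] / laid[ok]

    def cohort_juvenile_mortalities(self, burn_in_years: int = 5) -> np.ndarray:
        """Birth-to-pupation mortality of each natural cohort.

        Juveniles do not move, so the eggs laid in one cell during one year
        form a cohort whose survivors emerge in the same cell; the fraction
        that dies before completing the pupal stage is this cohort's
        mortality.  Cohorts differ strongly: those laid in crowded crop
        fields face heavy density-dependent larval mortality on top of the
        stage-wise background losses, while those in low-density refuge
        vegetation see mostly background mortality.  Returns one value per
        (cell, year) cohort after the burn-in.
        """
        laid = self.eggs_laid_by_cell_year
        emerged = self.adults_emerged_by_cell_year
        years = np.arange(laid.shape[1])
        sel = laid[:, years > burn_in_years]
        eme = emerged[:, years > burn_in_years]
        ok = sel > 0
        return 1.0 - eme[ok] / sel[ok]

    def trajectory_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.stage_counts, columns=["eggs", "larvae", "pupae", "adults"]
        )
        df.insert(0, "day", np.arange(self.n_days))
        df["q"] = self.q
        return df

    def treatments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.treatments, columns=["day", "cell", "compound", "trigger"]
        )

    def summary(self) -> dict:
        return {
            "outbreak_year": self.outbreak_year,
            "final_q": self.final_q,
            "n_treatments": len(self.treatments),
            "years": self.config.years,
            "scale": self.config.scale,
            "strategy": getattr(
                self.config.resolved_strategy(), "name", None
            ),
            "p_sosr": self.config.p_sosr,
            "dominance_w": self.config.resolved_compound().w,
        }


def allele_frequency(table: CohortTable):
    """R-allele frequency over all living individuals (None if empty)."""
    return allele_frequency_of(table.geno, table.count)


def detect_outbreak(
    q: np.ndarray, threshold: float = 0.5, persistence_days: int = 183
) -> Optional[int]:
    """First day starting an uninterrupted >=persistence run of q > threshold."""
    above = np.nan_to_num(q, nan=0.0) > threshold
    run = 0
    for day, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence_days:
            return day - persistence_days + 1
    return None


# ---------------------------------------------------------------------------
# Internal simulation state
# ---------------------------------------------------------------------------

_ADULT_MOBILE_PHASES = (AdultPhase.PRE_WINTER, AdultPhase.FEEDING, AdultPhase.REPRODUCING)


class _Sim:
    """One simulation run; see module docstring for the daily sub-step order."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.demography_seed)
        self.land = ls.generate_landscape(
            config.landscape_seed, config.composition, config.dims
        )
        self.crop_rng = np.random.default_rng(
            np.random.SeedSequence(config.landscape_seed).spawn(1)[0]
        )
        n_years = config.years
        self.weather = wx.generate_daily_weather(
            config.resolved_site(), n_years + 1, config.weather_seed
        )
        self.start_widx = wx.MIDSUMMER_DOY - 1  # 1 July of year 0
        self.n_days = n_years * wx.DAYS_PER_YEAR + (wx.DAYS_PER_YEAR - self.start_widx)
        self.strategy = config.resolved_strategy()
        self.compound = config.resolved_compound()
        self.suscept = genotype_susceptibility(self.compound)
        n = self.land.n_cells
        self.dist = self.land.distance_matrix()

        # seasonal triggers per calendar year
        self.spring_doy = {}
        self.autumn_doy = {}
        for y in range(n_years + 1):
            self.spring_doy[y] = wx.find_spring_emergence_day(self.weather, y)
            a = wx.find_autumn_return_day(self.weather, y)
            self.autumn_doy[y] = a if a is not None else wx.AUTUMN_FALLBACK_DOY

        # crop state per cell
        self.crop = np.full(n, int(ls.Crop.NONE), dtype=np.int8)
        self.pheno_state = np.zeros(n, dtype=np.int8)
        self.cum_dd = np.zeros(n)
        self.flowering_dd = np.zeros(n)
        self.flowering_onset = np.full(n, -1, dtype=np.int64)
        self.sow_day = np.full(n, -1, dtype=np.int64)
        self.season_treats: list[list] = [[] for _ in range(n)]
        self.active_treats: list[list] = [[] for _ in range(n)]
        self._plan_crops()

        # destination matrix for the autumn relocation (fixed all run)
        ow_attr = np.where(self.land.kind == ls.CellKind.OVERWINTER, 1.0, 0.0)
        self.ow_dest = destination_matrix(
            self.dist, ow_attr, config.movement.distance_exponent
        )

        n0 = int(round(config.initial_population * config.scale))
        self.pop = initialize_population(
            n0,
            config.initial_r_freq,
            self.land.cells_of_kind(ls.CellKind.OVERWINTER),
            self.rng,
        )

        # outputs
        self.q = np.full(self.n_days, np.nan)
        self.stage_counts = np.zeros((self.n_days, 4), dtype=np.int64)
        self.treatment_log: list = []
        self.eggs_laid_by_year = np.zeros(n_years + 1, dtype=np.int64)
        self.emerged_by_year = np.zeros(n_years + 1, dtype=np.int64)
        # per-cell ledgers: juveniles are immobile, so a (cell, year) pair
        # identifies a natural cohort from laying to adult emergence
        self.eggs_laid_by_cell_year = np.zeros((n, n_years + 1), dtype=np.int64)
        self.emerged_by_cell_year = np.zeros((n, n_years + 1), dtype=np.int64)
        self.old_age_deaths = 0

    # -- cropping ----------------------------------------------------------

    def _plan_crops(self) -> None:
        """Precompute sowing events (simulation day -> [(cell, crop)])."""
        self.sowings: dict[int, list] = {}
        arable = np.flatnonzero(self.land.kind == ls.CellKind.ARABLE)
        for y in range(1, self.cfg.years + 1):
            for cell in arable:
                plan = ls.plan_crop_for_year(
                    int(self.land.rotation_phase[cell]), y, self.crop_rng,
                    self.cfg.p_sosr,
                )
                if plan is None:
                    continue
                crop, doy_offset = plan
                abs_widx = y * wx.DAYS_PER_YEAR + doy_offset - 1
                sim_day = abs_widx - self.start_widx
                if 0 <= sim_day < self.n_days:
                    self.sowings.setdefault(sim_day, []).append((int(cell), int(crop)))

    def _sow_and_update_phenology(self, t: int, dd: float, day_length: float) -> None:
        p = self.cfg.phenology
        for cell, crop in self.sowings.get(t, ()):  # new sowings today
            self.crop[cell] = crop
            self.pheno_state[cell] = ls.PhenoState.SOWN
            self.cum_dd[cell] = 0.0
            self.flowering_dd[cell] = 0.0
            self.flowering_onset[cell] = -1
            self.sow_day[cell] = t
            self.season_treats[cell] = []
        growing = (
            (self.pheno_state >= ls.PhenoState.SOWN)
            & (self.pheno_state < ls.PhenoState.FINISHED)
            & (self.sow_day < t)  # thermal time accrues from the day after sowing
        )
        if not growing.any():
            return
        self.cum_dd[growing] += dd
        st = self.pheno_state
        emerge = growing & (st == ls.PhenoState.SOWN) & (self.cum_dd >= p.emergence_dd)
        st[emerge] = ls.PhenoState.EMERGED
        req = p.emergence_dd + np.where(
            self.crop == ls.Crop.SOSR, p.sosr_to_flowering_dd, p.wosr_to_flowering_dd
        )
        if day_length >= p.photoperiod_threshold_h:
            flower = growing & (st == ls.PhenoState.EMERGED) & (self.cum_dd >= req)
            st[flower] = ls.PhenoState.FLOWERING
            self.flowering_onset[flower] = t
        flowering = growing & (st == ls.PhenoState.FLOWERING)
        self.flowering_dd[flowering] += dd
        st[flowering & (self.flowering_dd >= p.flowering_duration_dd)] = (
            ls.PhenoState.FINISHED
        )

    # -- per-day cell descriptors -----------------------------------------

    def _host_arrays(self):
        """(host codes, plants per cell for adults, plants for larvae).

        Host code: 0 none, 1 flowering OSR, 2 wild refuge.  Larvae compete on
        the plants of any sown crop in the cell (competition continues after
        flowering ends), adults only where there is food (flowering OSR or
        wild refuge).
        """
        host = np.zeros(self.land.n_cells, dtype=np.int8)
        host[(self.land.kind == ls.CellKind.ARABLE)
             & (self.pheno_state == ls.PhenoState.FLOWERING)
             & np.isin(self.crop, (ls.Crop.WOSR, ls.Crop.SOSR))] = 1
        host[self.land.kind == ls.CellKind.REFUGE] = 2
        plants_adult = np.where(
            host == 1, ls.plants_per_cell("osr"),
            np.where(host == 2, ls.plants_per_cell("wild"), 0.0),
        )
        plants_larvae = np.where(
            (self.land.kind == ls.CellKind.ARABLE)
            & np.isin(self.crop, (ls.Crop.WOSR, ls.Crop.SOSR))
            & (self.pheno_state >= ls.PhenoState.SOWN),
            ls.plants_per_cell("osr"),
            np.where(self.land.kind == ls.CellKind.REFUGE,
                     ls.plants_per_cell("wild"), 0.0),
        )
        return host, plants_adult, plants_larvae

    def _counts_by_cell(self, mask: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.pop.cell[mask], weights=self.pop.count[mask],
            minlength=self.land.n_cells,
        )

    # -- daily sub-steps ----------------------------------------------------

    def _seasonal_transitions(self, doy: int, year: int) -> None:
        pop = self.pop
        if doy == self.spring_doy.get(year):
            over = pop.phase == AdultPhase.OVERWINTERING
            pop.phase[over] = AdultPhase.FEEDING
            pop.dd[over] = 0.0
        if doy == self.autumn_doy.get(year):
            # new generation relocates to overwintering sites and holds; the
            # spent parental generation dies with the season.  Juveniles are
            # left to finish development (a cold spell can fire the trigger
            # while the brood is still immature); any that emerge afterwards
            # relocate on emergence, and stragglers die at the winter-kill day.
            self._relocate_to_overwinter(
                np.flatnonzero(
                    (pop.stage == Stage.ADULT) & (pop.phase == AdultPhase.PRE_WINTER)
                )
            )
            spent = (pop.stage == Stage.ADULT) & np.isin(
                pop.phase, (AdultPhase.FEEDING, AdultPhase.REPRODUCING)
            )
            pop.count[spent] = 0
        if doy == wx.AUTUMN_FALLBACK_DOY:
            # immatures that have not reached adulthood by November die
            pop.count[pop.stage < Stage.ADULT] = 0

    def _relocate_to_overwinter(self, rows: np.ndarray) -> None:
        """Send the cohorts in ``rows`` to overwintering cells and put them
        into hibernation (destination ~ attractiveness / torus distance)."""
        pop = self.pop
        if rows.size == 0:
            return
        dests = self.rng.multinomial(pop.count[rows], self.ow_dest[pop.cell[rows]])
        src, dst = np.nonzero(dests)
        moved = pop.take(rows[src])
        moved.cell = dst.astype(np.int16)
        moved.count = dests[src, dst].astype(np.int64)
        moved.phase[:] = AdultPhase.OVERWINTERING
        moved.dd[:] = 0.0
        pop.count[rows] = 0
        self.pop = CohortTable.concat([pop, moved])

    def _decide_treatments(self, t: int, adult_density: np.ndarray) -> None:
        if self.strategy is None:
            return
        strat = self.strategy
        cand = np.flatnonzero(
            (self.pheno_state == ls.PhenoState.FLOWERING)
            & np.isin(self.crop, (ls.Crop.WOSR, ls.Crop.SOSR))
        )
        for cell in cand:
            days = self.season_treats[cell]
            if len(days) >= strat.max_treatments:
                continue
            fire = False
            trigger = strat.name
            if strat.mode == "calendar":
                onset = self.flowering_onset[cell]
                fire = any(t == onset + off for off in strat.calendar_offsets)
            else:
                threshold = strat.thresholds.get(
                    ls.Crop(self.crop[cell]).name, np.inf
                )
                if adult_density[cell] >= threshold:
                    interval = strat.retreat_interval(self.compound)
                    fire = all(t - prev >= interval for prev in days)
            if fire:
                days.append(t)
                self.active_treats[cell].append(t)
                self.treatment_log.append(
                    (t, int(cell), self.compound.name, trigger)
                )

    def _insecticide_mortality(self, t: int) -> None:
        pop = self.pop
        if pop.n == 0:
            return
        dose_by_cell = np.zeros(self.land.n_cells)
        any_active = False
        for cell in range(self.land.n_cells):
            evs = self.active_treats[cell]
            if not evs:
                continue
            evs = [ta for ta in evs if ta + self.compound.total_duration > t]
            self.active_treats[cell] = evs
            if evs:
                any_active = True
                dose_by_cell[cell] = dose_over_step(
                    t, t + 1.0, [(ta, self.compound) for ta in evs]
                )
        if not any_active:
            if pop.damage.any():
                pop.damage[:] = 0.0
            return
        dose = dose_by_cell[pop.cell]
        # contact insecticide: only foliage-active stages are exposed —
        # larvae feeding in flowers and adults; eggs (inside buds) and
        # pupae (in the soil) are concealed
        active = (pop.stage == Stage.LARVA) | (
            (pop.stage == Stage.ADULT) & (pop.phase != AdultPhase.OVERWINTERING)
        )
        exposed = (dose > 0) & active
        d_a = np.where(exposed, self.suscept[pop.geno] * dose, 0.0)
        p_kill = 1.0 - np.exp(-d_a)
        apply_mortality(pop, p_kill, self.rng)
        pop.damage[exposed] += d_a[exposed]
        pop.damage[~exposed] = 0.0  # reset where no treatment covers the cell

    def _natural_mortality(self, dd: float, host, plants_adult, plants_larvae) -> None:
        pop = self.pop
        if pop.n == 0:
            return
        cfg = self.cfg
        mp = cfg.mortality
        m = np.zeros(pop.n)
        juvenile = pop.stage < Stage.ADULT
        if juvenile.any():
            m_bg = background_mortality_step(
                mp.background_m, STAGE_DURATIONS_DD[np.minimum(pop.stage[juvenile], 2)], dd
            )
            m[juvenile] = m_bg
            larvae = pop.stage == Stage.LARVA
            if larvae.any():
                larv_cnt = self._counts_by_cell(larvae)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dens = np.where(
                        plants_larvae > 0, larv_cnt / (cfg.scale * plants_larvae), 0.0
                    )
                k = np.where(
                    host == 2, mp.k_larvae["wild"], mp.k_larvae["osr"]
                )
                m_dd_cell = density_mortality_step(
                    dens, k, mp.t_larvae_days, form=mp.density_form
                )
                rows = np.flatnonzero(larvae)
                m[rows] = combine_mortality(m[rows], m_dd_cell[pop.cell[rows]])
        adult = (pop.stage == Stage.ADULT) & np.isin(pop.phase, _ADULT_MOBILE_PHASES)
        if adult.any():
            ad_cnt = self._counts_by_cell(adult)
            with np.errstate(divide="ignore", invalid="ignore"):
                dens = np.where(
                    plants_adult > 0, ad_cnt / (cfg.scale * plants_adult), 0.0
                )
            k_pre = np.where(
                host == 2, mp.k_adult_pre_winter["wild"], mp.k_adult_pre_winter["osr"]
            )
            k_post = np.where(
                host == 2, mp.k_adult_post_winter["wild"], mp.k_adult_post_winter["osr"]
            )
            for phases, k_cell, t_days in (
                ((AdultPhase.PRE_WINTER,), k_pre, mp.t_adult_pre_winter_days),
                (
                    (AdultPhase.FEEDING, AdultPhase.REPRODUCING),
                    k_post,
                    mp.t_adult_post_winter_days,
                ),
            ):
                rows = np.flatnonzero(adult & np.isin(pop.phase, phases))
                if rows.size == 0:
                    continue
                cell = pop.cell[rows]
                m_dd = np.where(
                    plants_adult[cell] > 0,
                    density_mortality_step(
                        dens[cell], k_cell[cell], t_days, form=mp.density_form
                    ),
                    0.0,
                )
                m[rows] = combine_mortality(m[rows], m_dd)
        if m.any():
            apply_mortality(pop, m, self.rng)

    def _development(self, dd: float, year: int, autumn_passed: bool) -> None:
        pop = self.pop
        if pop.n == 0 or dd == 0:
            return
        juv = np.flatnonzero(pop.stage < Stage.ADULT)
        if juv.size:
            stage, new_dd, emerged = advance_development(
                pop.stage[juv], pop.dd[juv], dd
            )
            pop.stage[juv] = stage
            pop.dd[juv] = new_dd
            em = juv[emerged]
            if em.size:
                pop.phase[em] = AdultPhase.PRE_WINTER
                pop.dd[em] = 0.0
                self.emerged_by_year[year] += int(pop.count[em].sum())
                np.add.at(
                    self.emerged_by_cell_year[:, year], pop.cell[em], pop.count[em]
                )
                if autumn_passed:
                    # the season's relocation is over: head straight to the
                    # overwintering sites instead of lingering on dead hosts
                    self._relocate_to_overwinter(em)
                    pop = self.pop
        lh = self.cfg.life_history
        feeding = np.flatnonzero(
            (pop.stage == Stage.ADULT) & (pop.phase == AdultPhase.FEEDING)
        )
        if feeding.size:
            pop.dd[feeding] += dd
            done = feeding[pop.dd[feeding] >= lh.feeding_dd]
            pop.phase[done] = AdultPhase.REPRODUCING
            pop.dd[done] -= lh.feeding_dd
        repro = np.flatnonzero(
            (pop.stage == Stage.ADULT) & (pop.phase == AdultPhase.REPRODUCING)
        )
        if repro.size:
            pop.dd[repro] += dd
            spent = repro[pop.dd[repro] >= lh.reproduction_dd]
            self.old_age_deaths += int(pop.count[spent].sum())
            pop.count[spent] = 0  # old-age death at the end of the window

    def _mating_and_oviposition(self, dd: float, year: int) -> None:
        pop = self.pop
        lh = self.cfg.life_history
        males = (
            (pop.stage == Stage.ADULT)
            & (pop.phase == AdultPhase.REPRODUCING)
            & (pop.sex == 1)
        )
        virgins = np.flatnonzero(
            (pop.stage == Stage.ADULT)
            & (pop.phase == AdultPhase.REPRODUCING)
            & (pop.sex == 0)
            & (pop.mated == 0)
            & (pop.count > 0)
        )
        if virgins.size and males.any():
            male_geno_cnt = np.zeros((self.land.n_cells, 3))
            rows = np.flatnonzero(males)
            np.add.at(male_geno_cnt, (pop.cell[rows], pop.geno[rows]), pop.count[rows])
            male_tot = male_geno_cnt.sum(axis=1)
            density = male_tot / (self.cfg.scale * ls.CELL_AREA_M2)
            p = mating_probability(density[pop.cell[virgins]], 1.0, lh)
            n_mating = self.rng.binomial(pop.count[virgins], p)
            sel = n_mating > 0
            if sel.any():
                vrows = virgins[sel]
                splits = choose_mate_genotypes(
                    n_mating[sel], male_geno_cnt[pop.cell[vrows]], self.rng
                )
                pop.count[vrows] -= n_mating[sel]
                src, mg = np.nonzero(splits)
                mated = pop.take(vrows[src])
                mated.count = splits[src, mg].astype(np.int64)
                mated.mated[:] = 1
                mated.mate_geno = mg.astype(np.int16)
                mated.ovi_dd[:] = 0.0
                mated.batches[:] = 0
                self.pop = pop = CohortTable.concat([pop, mated])
        eggs = oviposition_step(pop, dd, self.rng, lh)
        if eggs.n:
            self.eggs_laid_by_year[year] += eggs.total()
            np.add.at(self.eggs_laid_by_cell_year[:, year], eggs.cell, eggs.count)
            self.pop = CohortTable.concat([pop, eggs])

    def _movement(self, host, adult_density: np.ndarray) -> None:
        pop = self.pop
        mobile = np.flatnonzero(
            (pop.stage == Stage.ADULT)
            & np.isin(pop.phase, _ADULT_MOBILE_PHASES)
            & (pop.count > 0)
        )
        if mobile.size == 0:
            return
        mv = self.cfg.movement
        p_move = np.ones(self.land.n_cells)
        for code, name in ((1, "osr"), (2, "wild")):
            cells = host == code
            d1, d2, d3, d4 = mv.density_knots[name]
            p_move[cells] = np.interp(
                adult_density[cells], [d1, d2, d3, d4],
                [mv.p_max[name], mv.p_min, mv.p_min, mv.p_max[name]],
            )
        attr = np.where(
            host == 1, mv.attractiveness["osr"],
            np.where(host == 2, mv.attractiveness["wild"], 0.0),
        )
        dest = destination_matrix(self.dist, attr, mv.distance_exponent)
        moved = execute_movements(pop, mobile, p_move, dest, self.rng)
        if moved.n:
            self.pop = CohortTable.concat([pop, moved])

    # -- main loop ----------------------------------------------------------

    def run(self) -> OutbreakResult:
        cfg = self.cfg
        run_above = 0
        outbreak_day = None
        for t in range(self.n_days):
            widx = self.start_widx + t
            doy = int(self.weather.doy[widx])
            year = int(self.weather.year[widx])
            tmean = float(self.weather.tmean[widx])
            day_length = float(self.weather.day_length[widx])
            dd = max(0.0, tmean)

            self._sow_and_update_phenology(t, dd, day_length)
            host, plants_adult, plants_larvae = self._host_arrays()
            adult_mask = (self.pop.stage == Stage.ADULT) & np.isin(
                self.pop.phase, _ADULT_MOBILE_PHASES
            )
            ad_cnt = self._counts_by_cell(adult_mask)
            with np.errstate(divide="ignore", invalid="ignore"):
                adult_density = np.where(
                    plants_adult > 0, ad_cnt / (cfg.scale * plants_adult), 0.0
                )
            self._seasonal_transitions(doy, year)
            self._decide_treatments(t, adult_density)
            self._insecticide_mortality(t)
            self._natural_mortality(dd, host, plants_adult, plants_larvae)
            autumn_passed = doy >= self.autumn_doy.get(year, wx.AUTUMN_FALLBACK_DOY)
            self._development(dd, year, autumn_passed)
            self._mating_and_oviposition(dd, year)
            self._movement(host, adult_density)
            self.pop = self.pop.compact(cfg.dd_bucket)

            counts = np.bincount(
                self.pop.stage, weights=self.pop.count, minlength=4
            ).astype(np.int64)
            self.stage_counts[t] = counts
            q = allele_frequency(self.pop)
            self.q[t] = np.nan if q is None else q
            above = q is not None and q > cfg.outbreak_threshold
            run_above = run_above + 1 if above else 0
            if outbreak_day is None and run_above >= cfg.outbreak_persistence_days:
                outbreak_day = t - cfg.outbreak_persistence_days + 1
                if cfg.stop_at_outbreak:
                    self.q = self.q[: t + 1]
                    self.stage_counts = self.stage_counts[: t + 1]
                    break
        return OutbreakResult(
            q=self.q,
            stage_counts=self.stage_counts,
            treatments=self.treatment_log,
            outbreak_day=outbreak_day,
            eggs_laid_by_year=self.eggs_laid_by_year,
            adults_emerged_by_year=self.emerged_by_year,
            eggs_laid_by_cell_year=self.eggs_laid_by_cell_year,
            adults_emerged_by_cell_year=self.emerged_by_cell_year,
            old_age_deaths=self.old_age_deaths,
            config=cfg,
        )


def run_simulation(config: SimulationConfig) -> OutbreakResult:
    """Run one full daily simulation and return its trajectories."""
    return _Sim(config).run()


# ---------------------------------------------------------------------------
# Monte Carlo harness
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloDesign:
    """Landscape x weather factorial, optionally over a scenario grid.

    ``scenarios`` maps a scenario label to config overrides (e.g.
    ``{"strategy": "C2", "p_sosr": 0.25, "dominance_w": 48.6}``); an empty
    dict runs the base configuration under label "base".
    """

    n_landscapes: int = 6
    n_weather_series: int = 6
    scenarios: dict = field(default_factory=lambda: {"base": {}})
    master_seed: int = 0

    @property
    def runs_per_scenario(self) -> int:
        return self.n_landscapes * self.n_weather_series


def _spawn_seeds(master_seed: int, label: str, n: int) -> list[int]:
    tag = zlib.crc32(label.encode())  # deterministic across processes
    ss = np.random.SeedSequence([master_seed, tag])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_monte_carlo(
    design: MonteCarloDesign, base_config: SimulationConfig
) -> pd.DataFrame:
    """Run the full landscape x weather grid for every scenario.

    Returns one row per run with the outbreak year (NaN if none within the
    horizon) and final allele frequency.  Landscape and weather seed axes are
    independent streams so the factorial structure is preserved; each run is
    reproducible from its seeds.
    """
    l_seeds = _spawn_seeds(design.master_seed, "landscape", design.n_landscapes)
    w_seeds = _spawn_seeds(design.master_seed, "weather", design.n_weather_series)
    d_seeds = _spawn_seeds(
        design.master_seed, "demography",
        design.n_landscapes * design.n_weather_series * len(design.scenarios),
    )
    records = []
    k = 0
    for label, overrides in design.scenarios.items():
        for i, lseed in enumerate(l_seeds):
            for j, wseed in enumerate(w_seeds):
                cfg = replace(
                    base_config,
                    landscape_seed=lseed,
                    weather_seed=wseed,
                    demography_seed=d_seeds[k],
                    **overrides,
                )
                k += 1
                res = run_simulation(cfg)
                records.append(
                    {
                        "scenario": label,
                        "landscape_rep": i,
                        "weather_rep": j,
                        "outbreak_year": (
                            np.nan if res.outbreak_year is None else res.outbreak_year
                        ),
                        "final_q": res.final_q,
                        "n_treatments": len(res.treatments),
                    }
                )
    return pd.DataFrame.from_records(records)


def summarize_monte_carlo(
    runs: pd.DataFrame, censor_years: Optional[float] = None
) -> pd.DataFrame:
    """Per-scenario min/quartiles/median/max/mean of years to outbreak.

    Runs without an outbreak are censored at ``censor_years`` when given
    (counted at the horizon), else dropped from the summary statistics.
    """
    df = runs.copy()
    if censor_years is not None:
        df["outbreak_year"] = df["outbreak_year"].fillna(censor_years)
    g = df.groupby("scenario")["outbreak_year"]
    out = g.agg(
        n="count",
        min="min",
        q1=lambda s: s.quantile(0.25),
        median="median",
        q3=lambda s: s.quantile(0.75),
        max="max",
        mean="mean",
    )
    out["n_no_outbreak"] = runs.groupby("scenario")["outbreak_year"].apply(
        lambda s: int(s.isna().sum())
    )
    return out
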