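"""Demographic core of the pollen-beetle population model.

The population is represented as *cohorts* (super-individuals): groups of
individuals identical in cell, life stage, adult phase, sex, genotype,
thermal age, mating state and accumulated insecticide damage, stored as
parallel numpy columns with an integer ``count``.  All stochastic fates
(mortality, mating, movement, offspring genotypes) are drawn binomially or
multinomially per cohort, which is exact in distribution for per-individual
rates, so a scaled-down population behaves statistically like a slice of the
full one.  A scaling factor maps the field-scale initial population (1e9
individuals) to desk-scale runs while leaving all per-plant and per-m^2
densities unchanged.

Life cycle (univoltine): adults overwinter in host-free habitat; a spring
temperature trigger releases them to feed for 400 degree-days, after which
they reproduce for 1000 degree-days and then die of old age.  Mated females
lay up to 10 egg batches, one per 85 degree-days, each of Uniform{15..35}
eggs (250 on average).  Eggs, larvae and pupae develop in 100, 250 and 600
degree-days (base 0 degC); new adults feed without mating and relocate to
overwintering sites at the autumn trigger.

Natural mortality has two independent competing components combined
multiplicatively on survival: a background (predation/parasitism) hazard
fixed per juvenile stage so the compounded per-step probabilities realise an
expected 33% loss per stage, and a density-dependent hazard that activates
above a threshold density K (insects per host plant) and drives a closed
cohort down to K in T days in expectation.  Eggs and pupae are exempt from
density mortality; adults (from pupation) are subject only to density
mortality and old age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd


class Genotype(IntEnum):
    """Single-locus resistance genotype, coded by R-allele count."""

    SS = 0
    RS = 1
    RR = 2


class Stage(IntEnum):
    EGG = 0
    LARVA = 1
    PUPA = 2
    ADULT = 3


class AdultPhase(IntEnum):
    NONE = -1          # juveniles
    PRE_WINTER = 0     # new generation feeding before hibernation
    OVERWINTERING = 1
    FEEDING = 2        # post-winter maturation feeding (400 dd)
    REPRODUCING = 3    # 1000 dd reproduction window
    SENESCENT = 4


#: Juvenile stage durations in degree-days (EGG, LARVA, PUPA).
STAGE_DURATIONS_DD = np.array([100.0, 250.0, 600.0])


@dataclass(frozen=True)
class LifeHistoryParams:
    feeding_dd: float = 400.0
    reproduction_dd: float = 1000.0
    batch_interval_dd: float = 85.0
    max_batches: int = 10
    eggs_min: int = 15
    eggs_max: int = 35
    t50_mating_days: float = 3.0
    d50_mating_per_m2: float = 25.0

    def __post_init__(self):
        if self.eggs_min > self.eggs_max:
            raise ValueError("eggs_min must not exceed eggs_max")


@dataclass(frozen=True)
class MortalityParams:
    """Background and density-dependent mortality parameters.

    ``background_m`` is the expected total mortality over each juvenile stage
    (egg, larva, pupa); K thresholds are insects per host plant, T decline
    times in days.  The wild-refuge thresholds are 0.625x the crop values,
    reflecting that only part of the wild flora hosts the beetle.
    """

    background_m: float = 0.33
    k_larvae: dict = field(
        default_factory=lambda: {"osr": 100.0, "wild": 62.0}
    )
    t_larvae_days: float = 5.0
    k_adult_pre_winter: dict = field(
        default_factory=lambda: {"osr": 100.0, "wild": 62.0}
    )
    k_adult_post_winter: dict = field(
        default_factory=lambda: {"osr": 70.0, "wild": 44.0}
    )
    t_adult_pre_winter_days: float = 100.0
    t_adult_post_winter_days: float = 50.0
    #: functional form of density mortality; see density_mortality_step
    density_form: str = "excess"

    def __post_init__(self):
        if not 0 <= self.background_m < 1:
            raise ValueError("background_m must be in [0, 1)")
        if self.density_form not in ("excess", "power"):
            raise ValueError("density_form must be 'excess' or 'power'")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

_INT_COLS = ("cell", "stage", "phase", "sex", "geno", "mated", "mate_geno", "batches")
_FLOAT_COLS = ("dd", "ovi_dd", "damage")


class CohortTable:
    """Column-store of cohorts with integer counts.

    Columns: cell, stage, phase, sex (0=F, 1=M), geno (R-allele count),
    mated flag, mate_geno (-1 if unmated), batches laid, dd (thermal age in
    the current stage/phase), ovi_dd (thermal time since mating, drives the
    batch clock), damage (accumulated insecticide damage), count.
    """

    __slots__ = _INT_COLS + _FLOAT_COLS + ("count",)

    def __init__(self, n: int = 0):
        for col in _INT_COLS:
            setattr(self, col, np.zeros(n, dtype=np.int16))
        for col in _FLOAT_COLS:
            setattr(self, col, np.zeros(n, dtype=np.float64))
        self.count = np.zeros(n, dtype=np.int64)
        self.mate_geno = np.full(n, -1, dtype=np.int16)
        self.phase = np.full(n, int(AdultPhase.NONE), dtype=np.int16)

    @property
    def n(self) -> int:
        return self.count.size

    def total(self) -> int:
        return int(self.count.sum())

    def copy(self) -> "CohortTable":
        out = CohortTable(0)
        for col in _INT_COLS + _FLOAT_COLS + ("count",):
            setattr(out, col, getattr(self, col).copy())
        return out

    def take(self, idx) -> "CohortTable":
        out = CohortTable(0)
        for col in _INT_COLS + _FLOAT_COLS + ("count",):
            setattr(out, col, getattr(self, col)[idx])
        return out

    @staticmethod
    def concat(tables: list["CohortTable"]) -> "CohortTable":
        tables = [t for t in tables if t.n]
        if not tables:
            return CohortTable(0)
        out = CohortTable(0)
        for col in _INT_COLS + _FLOAT_COLS + ("count",):
            setattr(out, col, np.concatenate([getattr(t, col) for t in tables]))
        return out

    def compact(self, dd_bucket: float = 5.0, damage_bucket: float = 0.01) -> "CohortTable":
        """Merge cohorts identical up to thermal-age/damage bucketing.

        Grouping keys are the integer columns plus dd, ovi_dd and damage
        quantised to buckets; within a group float columns are count-weighted
        means.  Zero-count rows are dropped.
        """
        alive = self.count > 0
        t = self.take(alive) if not alive.all() else self
        if t.n <= 1:
            return t
        keys = np.empty((t.n, len(_INT_COLS) + 3), dtype=np.int64)
        for j, col in enumerate(_INT_COLS):
            keys[:, j] = getattr(t, col)
        keys[:, -3] = np.floor(t.dd / dd_bucket)
        keys[:, -2] = np.floor(t.ovi_dd / dd_bucket)
        keys[:, -1] = np.floor(t.damage / damage_bucket)
        view = np.ascontiguousarray(keys).view(
            np.dtype((np.void, keys.dtype.itemsize * keys.shape[1]))
        ).ravel()
        _, first, inv = np.unique(view, return_index=True, return_inverse=True)
        k = first.size
        if k == t.n:
            return t
        out = CohortTable(0)
        for col in _INT_COLS:
            setattr(out, col, getattr(t, col)[first])
        counts = np.bincount(inv, weights=t.count, minlength=k)
        for col in _FLOAT_COLS:
            sums = np.bincount(inv, weights=t.count * getattr(t, col), minlength=k)
            setattr(out, col, sums / counts)
        out.count = counts.astype(np.int64)
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {col: getattr(self, col) for col in _INT_COLS + _FLOAT_COLS}
        data["count"] = self.count
        df = pd.DataFrame(data)
        df["stage"] = [Stage(s).name for s in self.stage]
        df["geno"] = [Genotype(g).name for g in self.geno]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genetics
# ---------------------------------------------------------------------------

def offspring_genotype_distribution(maternal: int, paternal: int) -> np.ndarray:
    """Mendelian single-locus offspring distribution over (SS, RS, RR)."""
    pm = maternal / 2.0
    pf = paternal / 2.0
    rr = pm * pf
    ss = (1.0 - pm) * (1.0 - pf)
    return np.array([ss, 1.0 - ss - rr, rr])


#: MENDEL[m, f] = offspring_genotype_distribution(m, f) for all 9 crosses.
MENDEL = np.array(
    [[offspring_genotype_distribution(m, f) for f in range(3)] for m in range(3)]
)


def hardy_weinberg_probs(q: float) -> np.ndarray:
    """Genotype probabilities ((1-q)^2, 2q(1-q), q^2) at allele frequency q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def allele_frequency_of(geno: np.ndarray, count: np.ndarray):
    """R-allele frequency (2*RR + RS) / (2*N); None for an empty population."""
    total = count.sum()
    if total == 0:
        return None
    return float((geno * count).sum() / (2.0 * total))


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def initialize_population(
    n: int, q0: float, overwinter_cells: np.ndarray, rng: np.random.Generator
) -> CohortTable:
    """Seed ``n`` hibernating adults over the overwintering cells.

    Genotypes follow Hardy-Weinberg at allele frequency ``q0``, sex is
    Bernoulli(1/2), and placement is uniform over overwintering cells; the
    joint allocation is a single multinomial draw over cell x genotype x sex.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cells = np.asarray(overwinter_cells)
    if cells.size == 0:
        raise ValueError("landscape has no overwintering cells")
    hw = hardy_weinberg_probs(q0)
    probs = (
        np.full((cells.size, 1, 1), 1.0 / cells.size)
        * hw[None, :, None]
        * np.array([0.5, 0.5])[None, None, :]
    )
    draws = rng.multinomial(n, probs.ravel()).reshape(cells.size, 3, 2)
    idx = np.argwhere(draws > 0)
    t = CohortTable(idx.shape[0])
    t.cell = cells[idx[:, 0]].astype(np.int16)
    t.geno = idx[:, 1].astype(np.int16)
    t.sex = idx[:, 2].astype(np.int16)
    t.stage = np.full(t.n, int(Stage.ADULT), dtype=np.int16)
    t.phase = np.full(t.n, int(AdultPhase.OVERWINTERING), dtype=np.int16)
    t.count = draws[idx[:, 0], idx[:, 1], idx[:, 2]]
    return t


# ---------------------------------------------------------------------------
# Development
# ---------------------------------------------------------------------------

def advance_development(
    stage: np.ndarray, dd: np.ndarray, dd_step: float,
    durations: np.ndarray = STAGE_DURATIONS_DD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance juvenile thermal age, carrying remainders across stages.

    Returns (new_stage, new_dd, emerged_mask); rows whose pupal stage
    completes become adults (caller sets the adult phase).  Degree-days in
    excess of a stage duration carry into the next stage, so emergence timing
    under constant temperature matches closed-form arithmetic exactly.
    """
    if dd_step < 0:
        raise ValueError("dd_step must be non-negative")
    stage = stage.astype(np.int16).copy()
    dd = dd + dd_step
    while True:
        juvenile = stage < Stage.ADULT
        over = juvenile & (dd >= durations[np.minimum(stage, 2)])
        if not over.any():
            break
        dd[over] -= durations[stage[over]]
        stage[over] += 1
    emerged = stage == Stage.ADULT
    return stage, dd, emerged


# ---------------------------------------------------------------------------
# Mating and reproduction
# ---------------------------------------------------------------------------

def mating_probability(
    male_density: np.ndarray | float, dt_days: float, params: LifeHistoryParams
) -> np.ndarray | float:
    """Per-step mating probability of a virgin female.

    Exponential hazard in (male density x time), normalised so the cumulative
    mated fraction reaches 50% after t50 days at density d50:
    ``p = 1 - 0.5 ** ((d / d50) * (dt / t50))``.  Memoryless and monotone in
    density.
    """
    d = np.asarray(male_density, dtype=float)
    if np.any(d < 0):
        raise ValueError("male density must be non-negative")
    expo = (d / params.d50_mating_per_m2) * (dt_days / params.t50_mating_days)
    out = 1.0 - np.power(0.5, expo)
    return float(out) if np.isscalar(male_density) else out


def choose_mate_genotypes(
    n_females: np.ndarray, male_counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split newly mated females by partner genotype.

    ``male_counts`` has one row of (SS, RS, RR) male counts per female
    cohort; rows are multinomial draws proportional to those counts.
    """
    male_counts = np.atleast_2d(male_counts).astype(float)
    totals = male_counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("no males present in cell")
    return rng.multinomial(np.asarray(n_females), male_counts / totals)


def sample_batch_eggs(
    n_females: np.ndarray, rng: np.random.Generator,
    lo: int = 15, hi: int = 35,
) -> np.ndarray:
    """Total eggs laid by ``n_females`` each drawing Uniform{lo..hi}.

    Exact sums for small cohorts; a clipped normal approximation to the sum
    (mean 25 n, variance n*((hi-lo+1)^2-1)/12) for large ones.
    """
    n_females = np.asarray(n_females, dtype=np.int64)
    out = np.zeros(n_females.shape, dtype=np.int64)
    small = n_females <= 512
    for i in np.flatnonzero(small):
        out[i] = rng.integers(lo, hi + 1, size=n_females[i]).sum()
    big = ~small
    if big.any():
        n = n_females[big]
        mean = 0.5 * (lo + hi) * n
        var = n * (((hi - lo + 1) ** 2 - 1) / 12.0)
        draw = np.rint(rng.normal(mean, np.sqrt(var)))
        out[big] = np.clip(draw, lo * n, hi * n).astype(np.int64)
    return out


def oviposition_step(
    table: CohortTable, dd_step: float, rng: np.random.Generator,
    params: LifeHistoryParams | None = None,
) -> CohortTable:
    """Advance the batch clock of mated reproducing females and lay eggs.

    One batch is due per 85 degree-days since mating, capped at 10 batches
    per female; each batch is Uniform{15..35} eggs placed in the mother's
    current cell, with genotypes multinomial from the Mendelian cross of the
    mother and her stored mate genotype and sex Bernoulli(1/2).  Mutates the
    female cohorts' clocks in place and returns the new egg cohorts.
    """
    params = params or LifeHistoryParams()
    laying = (
        (table.stage == Stage.ADULT)
        & (table.phase == AdultPhase.REPRODUCING)
        & (table.sex == 0)
        & (table.mated == 1)
        & (table.batches < params.max_batches)
        & (table.count > 0)
    )
    idx = np.flatnonzero(laying)
    table.ovi_dd[idx] += dd_step
    eggs_parts: list[CohortTable] = []
    while True:
        due = idx[
            (table.ovi_dd[idx] >= params.batch_interval_dd)
            & (table.batches[idx] < params.max_batches)
        ]
        if due.size == 0:
            break
        table.ovi_dd[due] -= params.batch_interval_dd
        table.batches[due] += 1
        totals = sample_batch_eggs(
            table.count[due], rng, params.eggs_min, params.eggs_max
        )
        geno_probs = MENDEL[table.geno[due], table.mate_geno[due]]
        # joint split over genotype x sex
        probs6 = np.repeat(geno_probs, 2, axis=1) * 0.5
        split = rng.multinomial(totals, probs6)  # (n_due, 6)
        rows = np.argwhere(split > 0)
        part = CohortTable(rows.shape[0])
        part.cell = table.cell[due][rows[:, 0]]
        part.geno = (rows[:, 1] // 2).astype(np.int16)
        part.sex = (rows[:, 1] % 2).astype(np.int16)
        part.stage = np.zeros(rows.shape[0], dtype=np.int16)  # EGG
        part.count = split[rows[:, 0], rows[:, 1]].astype(np.int64)
        eggs_parts.append(part)
    return CohortTable.concat(eggs_parts)


# ---------------------------------------------------------------------------
# Natural mortality
# ---------------------------------------------------------------------------

def background_mortality_step(M: float, D: float, dd_step) -> np.ndarray | float:
    """Per-step background mortality compounding to M over a full stage.

    ``m = 1 - (1 - M) ** (dd_step / D)`` with D the stage duration in
    degree-days, so the survival over any partition of the stage multiplies
    to exactly 1 - M.
    """
    if not 0 <= M < 1:
        raise ValueError("M must be in [0, 1)")
    if np.any(np.asarray(D) <= 0):
        raise ValueError("stage duration must be positive")
    return 1.0 - np.power(1.0 - M, np.asarray(dd_step, dtype=float) / np.asarray(D, dtype=float))


def density_mortality_step(
    density, K: float, T: float, dt_days: float = 1.0, form: str = "excess"
) -> np.ndarray | float:
    """Density-dependent per-step mortality above the threshold K.

    Zero at or below K.  Above it, two functional forms realise the stated
    semantics "a closed cohort at density d declines to K in T days":

    - ``"excess"`` (default): the expected number of deaths per day is the
      excess over the threshold spread over T days, ``(d - K) / T``, i.e. a
      per-individual mortality ``(1 - K/d) * dt/T``.  A closed cohort
      declines *linearly* to K, reaching it after exactly T days from any
      starting density, and the daily mortality is bounded by dt/T however
      crowded the cell — removal of the excess, not collapse of the whole
      pool.
    - ``"power"``: survival ``(K / d) ** (dt / T)``, a geometric decline
      that also reaches K after T days but compounds without bound when
      recruitment holds the density far above K.
    """
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("K must be positive")
    if T < 1:
        raise ValueError("T must be >= 1 day")
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    safe = np.maximum(d, K)
    if form == "excess":
        m = np.where(d <= K, 0.0, (1.0 - K / safe) * (dt_days / T))
    elif form == "power":
        with np.errstate(divide="ignore"):
            m = np.where(d <= K, 0.0, 1.0 - np.power(K / safe, dt_days / T))
    else:
        raise ValueError("form must be 'excess' or 'power'")
    return float(m) if np.isscalar(density) and K.ndim == 0 else m


def combine_mortality(m_background, m_density) -> np.ndarray | float:
    """Overall step mortality from independent competing risks."""
    return 1.0 - (1.0 - np.asarray(m_background)) * (1.0 - np.asarray(m_density))


def apply_mortality(
    table: CohortTable, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw binomial deaths per cohort; returns deaths and updates counts."""
    p = np.clip(p, 0.0, 1.0)
    deaths = rng.binomial(table.count, p)
    table.count -= deaths
    return deaths
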