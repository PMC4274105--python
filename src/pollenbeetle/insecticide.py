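"""Insecticide efficacy, exposure, genotype-specific mortality and treatment
decisions.

A treatment's efficacy is 1 for ``Dmax`` days after application, then
declines linearly to 0 over ``Ddecl`` days.  Exposure follows Haber's rule:
the dose an insect receives over a step is the time-integral of efficacy of
every active treatment in its cell.  Dose is converted to damage through a
genotype-specific susceptibility factor S; damage accumulates while the
insect remains exposed and maps to mortality through a cumulative-hazard
law, ``P(damage A) = 1 - exp(-A)``, whose per-step conditional kill
probability ``1 - exp(-dA)`` is invariant to how a step is partitioned.
Damage resets to zero once no treatment is active in the insect's cell.

Heterozygote susceptibility is a dominance-weighted average of the
homozygotes: ``S_RS = (w * S_RR + S_SS) / (w + 1)``; w = 0 makes resistance
completely recessive, w = 1 intermediate, large w dominant.  The
lambda-cyhalothrin preset carries the field-trial-calibrated values
(Dmax 4.7 d, Ddecl 6 d, S_SS 0.86, S_RR 0.003, w 48.6); the pymetrozine
preset (Dmax 1.5 d, Ddecl 10.6 d, S_SS 0.72) shares the resistance-allele
parameters for sensitivity runs.

Farmers either spray on calendar dates (fixed offsets after the field's
flowering onset) or when scouted adult density exceeds a per-crop threshold,
with at most two treatments per field per season.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class Compound:
    name: str
    d_max: float      # days of maximum efficacy
    d_decl: float     # days of linear decline from 1 to 0
    s_ss: float       # susceptibility of SS homozygotes
    s_rr: float       # susceptibility of RR homozygotes
    w: float          # dominance weight of the R allele

    def __post_init__(self):
        if self.d_max < 0 or self.d_decl < 0:
            raise ValueError("durations must be non-negative")
        if self.s_ss < 0 or self.s_rr < 0 or self.w < 0:
            raise ValueError("susceptibilities and dominance must be non-negative")

    @property
    def total_duration(self) -> float:
        return self.d_max + self.d_decl

    def with_dominance(self, w: float) -> "Compound":
        return replace(self, w=w)


LAMBDA_CYHALOTHRIN = Compound("lambda-cyhalothrin", 4.7, 6.0, 0.86, 0.003, 48.6)
PYMETROZINE = Compound("pymetrozine", 1.5, 10.6, 0.72, 0.003, 48.6)

COMPOUND_PRESETS = {c.name: c for c in (LAMBDA_CYHALOTHRIN, PYMETROZINE)}


@dataclass(frozen=True)
class TreatmentEvent:
    cell: int
    application_day: float
    compound: Compound


def efficacy_at(t, application_day: float, compound: Compound):
    """Efficacy at time t: 1 on the plateau, linear decline to 0, else 0."""
    x = np.asarray(t, dtype=float) - application_day
    out = np.where(
        x < 0,
        0.0,
        np.where(
            x <= compound.d_max,
            1.0,
            np.where(
                x <= compound.total_duration,
                1.0 - (x - compound.d_max) / compound.d_decl if compound.d_decl > 0 else 0.0,
                0.0,
            ),
        ),
    )
    return float(out) if np.isscalar(t) else out


def _efficacy_integral_from_start(x, compound: Compound):
    """Integral of efficacy over [application, application + x], closed form."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    plateau = np.minimum(x, compound.d_max)
    y = np.clip(x - compound.d_max, 0.0, compound.d_decl)
    if compound.d_decl > 0:
        tri = y - y * y / (2.0 * compound.d_decl)
    else:
        tri = np.zeros_like(y)
    return plateau + tri


def dose_over_step(t0: float, t1: float, treatments) -> float:
    """Haber's-rule dose over [t0, t1]: summed exact efficacy integrals.

    ``treatments`` is an iterable of TreatmentEvent (or (day, compound)
    pairs) active in the insect's cell.
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    dose = 0.0
    for ev in treatments:
        ta, compound = (
            (ev.application_day, ev.compound)
            if isinstance(ev, TreatmentEvent)
            else ev
        )
        dose += float(
            _efficacy_integral_from_start(t1 - ta, compound)
            - _efficacy_integral_from_start(t0 - ta, compound)
        )
    return dose


def genotype_susceptibility(compound: Compound, genotype=None):
    """Susceptibility factor(s); heterozygote is the dominance-weighted mean.

    With ``genotype`` None, returns the (S_SS, S_RS, S_RR) array indexed by
    R-allele count.
    """
    s_rs = (compound.w * compound.s_rr + compound.s_ss) / (compound.w + 1.0)
    s = np.array([compound.s_ss, s_rs, compound.s_rr])
    if genotype is None:
        return s
    return s[np.asarray(genotype, dtype=int)]


def kill_probability_step(S, dose_step, prior_damage=0.0):
    """Per-step kill probability and updated damage under the hazard law.

    Damage increment is ``S * dose_step``; the conditional kill probability
    of a survivor is ``1 - exp(-increment)``, so cumulative survival over any
    partition of an exposure window is exp(-total damage).
    """
    dose_step = np.asarray(dose_step, dtype=float)
    if np.any(dose_step < 0):
        raise ValueError("dose must be non-negative")
    inc = np.asarray(S, dtype=float) * dose_step
    return 1.0 - np.exp(-inc), np.asarray(prior_damage, dtype=float) + inc


@dataclass(frozen=True)
class ControlStrategy:
    """Treatment decision rule for one field-season.

    CALENDAR mode sprays at fixed day offsets after the field's own
    flowering onset; THRESHOLD mode sprays whenever scouted adult density
    (insects/plant, checked daily during flowering) reaches the crop's
    threshold, subject to a minimum re-treatment interval.  Both modes are
    capped at ``max_treatments`` per field per season.
    """

    name: str
    mode: str  # "calendar" | "threshold"
    calendar_offsets: tuple = ()
    thresholds: dict | None = None  # crop name -> insects/plant
    max_treatments: int = 2
    min_retreat_interval: float | None = None  # defaults to Dmax + Ddecl

    def __post_init__(self):
        if self.mode not in ("calendar", "threshold"):
            raise ValueError("mode must be 'calendar' or 'threshold'")
        if any(o <= 0 for o in self.calendar_offsets):
            raise ValueError("calendar offsets must be positive")
        if self.thresholds and any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be positive")

    def retreat_interval(self, compound: Compound) -> float:
        if self.min_retreat_interval is not None:
            return self.min_retreat_interval
        return compound.total_duration


#: The four management strategies of the scenario factorial: one or two
#: calendar sprays, or the recommended high / reduced low density thresholds.
STRATEGY_PRESETS = {
    "C1": ControlStrategy("C1", "calendar", calendar_offsets=(10,)),
    "C2": ControlStrategy("C2", "calendar", calendar_offsets=(10, 20)),
    "HT": ControlStrategy("HT", "threshold", thresholds={"WOSR": 15.0, "SOSR": 5.0}),
    "LT": ControlStrategy("LT", "threshold", thresholds={"WOSR": 5.0, "SOSR": 5.0}),
}


def decide_treatment(
    strategy: ControlStrategy,
    *,
    crop: str,
    day: float,
    flowering_onset_day: float | None,
    adult_density: float,
    season_treatment_days: list,
    compound: Compound,
) -> bool:
    """Whether a new treatment fires in this field today.

    Calendar sprays fire on each configured offset after flowering onset;
    threshold sprays fire when density reaches the crop threshold and the
    re-treatment interval has elapsed.  Never more than ``max_treatments``
    per season.
    """
    if len(season_treatment_days) >= strategy.max_treatments:
        return False
    if flowering_onset_day is None:
        return False
    if strategy.mode == "calendar":
        return any(
            day == flowering_onset_day + off for off in strategy.calendar_offsets
        )
    threshold = strategy.thresholds.get(crop)
    if threshold is None or adult_density < threshold:
        return False
    interval = strategy.retreat_interval(compound)
    return all(day - prev >= interval for prev in season_treatment_days)
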