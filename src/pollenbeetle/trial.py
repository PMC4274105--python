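"""Virtual plot-trial harness for compound calibration.

Field efficacy trials divide a field into plots; some are left untreated
(check plots), the rest sprayed at field rates, and control is measured as
the percentage reduction in insect counts in treated plots relative to the
checks.  The virtual analogue simulates one field of 3 check + 3 treated
plots with 150,000 adults placed at random, genotypes drawn Hardy-Weinberg
at a configured resistance-allele frequency (0.5%, 25% and 55% for the low /
moderate / high resistance classes).  Insects move between plots with a
fixed daily probability of 40%, the destination chosen uniformly among the
other plots with no distance effect; insecticide mortality applies in the
treated plots only.  No natural mortality is simulated inside a trial: it
would apply equally to both arms and cancels from the control ratio in
expectation.

The calibration objective is the normalised root-mean-square error (RMSE
divided by the mean observed control) between observed and simulated daily
control curves, averaged over resistance levels.  The optimiser is pluggable;
the default is scipy's differential evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .insecticide import Compound, dose_over_step, genotype_susceptibility
from .population import hardy_weinberg_probs


@dataclass(frozen=True)
class TrialConfig:
    n_plots_per_arm: int = 3
    initial_insects: int = 150_000
    initial_r_freq: float = 0.005
    daily_move_prob: float = 0.40
    duration_days: int = 15  # covers the full lambda-cyhalothrin span (10.7 d)

    def __post_init__(self):
        if not 0 <= self.daily_move_prob <= 1:
            raise ValueError("daily_move_prob must be a probability")
        if not 0 <= self.initial_r_freq <= 1:
            raise ValueError("initial_r_freq must be a frequency")


@dataclass
class ControlCurve:
    """Daily % control (reduction in treated-plot counts relative to checks)."""

    day: np.ndarray
    control: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.day, "control": self.control})


def control_metric(treated_count: float, check_count: float) -> float:
    """% control = 100 * (1 - treated / check); NaN if the check is empty."""
    if check_count <= 0:
        return float("nan")
    return 100.0 * (1.0 - treated_count / check_count)


def simulate_trial(
    config: TrialConfig, compound: Compound, seed
) -> ControlCurve:
    """Simulate one virtual trial; individual-level sampling throughout.

    The treatment is applied to the treated plots at time 0; day d covers
    [d-1, d].  Within a day, insecticide mortality comes first, the daily
    plot counts (and hence control) are recorded, and movement happens last —
    movement is instantaneous at the end of the step, after the day's
    scouting.
    """
    rng = np.random.default_rng(seed)
    n_plots = 2 * config.n_plots_per_arm
    treated = np.arange(n_plots) < config.n_plots_per_arm  # plots 0..2 treated
    n = config.initial_insects
    plot = rng.integers(0, n_plots, size=n)
    geno = rng.choice(3, size=n, p=hardy_weinberg_probs(config.initial_r_freq))
    suscept = genotype_susceptibility(compound)
    alive = np.ones(n, dtype=bool)

    days = np.arange(1, config.duration_days + 1)
    control = np.empty(days.size)
    for i, d in enumerate(days):
        dose = dose_over_step(float(d - 1), float(d), [(0.0, compound)])
        if dose > 0:
            exposed = alive & treated[plot]
            p_kill = 1.0 - np.exp(-suscept[geno[exposed]] * dose)
            alive[np.flatnonzero(exposed)[rng.random(int(exposed.sum())) < p_kill]] = (
                False
            )
        counts = np.bincount(plot[alive], minlength=n_plots)
        mean_treated = counts[treated].mean()
        mean_check = counts[~treated].mean()
        control[i] = control_metric(mean_treated, mean_check)
        movers = alive & (rng.random(n) < config.daily_move_prob)
        idx = np.flatnonzero(movers)
        # uniform among the other plots, no distance effect
        shift = rng.integers(1, n_plots, size=idx.size)
        plot[idx] = (plot[idx] + shift) % n_plots
    return ControlCurve(day=days, control=control)


def nrmse(observed: np.ndarray, simulated: np.ndarray) -> float:
    """RMSE normalised by the mean of the observed values.

    Curves must share a day grid; NaNs in either curve are dropped pairwise.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("curves must share a common day grid")
    ok = ~(np.isnan(obs) | np.isnan(sim))
    if not ok.any():
        raise ValueError("no overlapping observations")
    obs, sim = obs[ok], sim[ok]
    return float(np.sqrt(np.mean((obs - sim) ** 2)) / np.mean(obs))


#: Resistance-allele frequencies of the three field-trial resistance classes.
RESISTANCE_LEVEL_FREQS = (0.005, 0.25, 0.55)

_PARAM_ORDER = ("d_max", "d_decl", "s_ss", "s_rr", "w")


def calibrate_compound(
    observed: dict[float, ControlCurve | tuple],
    bounds: dict[str, tuple],
    seed,
    base_compound: Compound | None = None,
    trial_config: TrialConfig | None = None,
    n_reps: int = 2,
    optimizer=None,
    optimizer_kwargs: dict | None = None,
):
    """Fit compound parameters to observed control curves.

    ``observed`` maps an initial R frequency to its daily control curve;
    ``bounds`` maps any of d_max, d_decl, s_ss, s_rr, w to (lo, hi) —
    parameters without bounds are held at ``base_compound``'s values.  The
    objective is the mean nRMSE over resistance levels, each simulated as
    the average of ``n_reps`` seeded virtual trials.  ``optimizer`` may be
    any callable with the signature of
    ``scipy.optimize.differential_evolution`` (the default).

    Returns (fitted Compound, objective value).
    """
    if not observed:
        raise ValueError("at least one observed curve is required")
    free = [p for p in _PARAM_ORDER if p in bounds]
    if not free:
        raise ValueError("no free parameters given in bounds")
    base = base_compound or Compound("candidate", 4.0, 6.0, 0.5, 0.01, 1.0)
    cfg = trial_config or TrialConfig()
    curves = {}
    for freq, curve in observed.items():
        arr = curve.control if isinstance(curve, ControlCurve) else np.asarray(curve[1])
        ndays = (
            curve.day.size if isinstance(curve, ControlCurve) else len(curve[0])
        )
        curves[freq] = np.asarray(arr, dtype=float)
        if ndays != cfg.duration_days:
            raise ValueError("observed curve length must match trial duration")
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_reps)]
    opt_seed = int(ss.generate_state(1)[0] % 2**31)

    def build(x):
        params = {p: v for p, v in zip(free, x)}
        return replace(base, **params)

    def objective(x):
        compound = build(x)
        errors = []
        for freq, obs in curves.items():
            sims = [
                simulate_trial(replace(cfg, initial_r_freq=freq), compound, s).control
                for s in trial_seeds
            ]
            errors.append(nrmse(obs, np.mean(sims, axis=0)))
        return float(np.mean(errors))

    opt = optimizer or differential_evolution
    kwargs = dict(seed=opt_seed, maxiter=30, popsize=8, tol=1e-3, polish=False)
    kwargs.update(optimizer_kwargs or {})
    result = opt(objective, [bounds[p] for p in free], **kwargs)
    return build(result.x), float(result.fun)
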