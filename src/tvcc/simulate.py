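"""Synthetic data generator for the waning-vaccine-efficacy study design.

The generator emulates a population-based case-control study of infant BCG
vaccination and tuberculosis: five birth cohorts spanning 1984-2012 with
cohort-specific vaccination uptake, piecewise-exponential TB incidence by
5-year age band, a vaccine hazard ratio of 0.25 during the first 5 years
since vaccination that rises by 35% every subsequent 5 years, events
observable only from 2003 (left truncation), follow-up censored at the end
of 2013, cases capped at age 19, and controls frequency matched to cases
within birth cohorts.

All times are continuous calendar years ("end of 2013" is 2014.0); event
ages are drawn by inverting the piecewise-linear cumulative hazard, so the
sampler is exact, vectorised and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import validate_subjects
from .errors import ConfigurationError, SimulationError

__all__ = [
    "SimulationConfig",
    "hr_at",
    "simulate_cohort",
    "apply_study_window",
    "sample_case_control",
    "simulate_case_control",
    "calibrate_cohort_sizes",
]

#: Default cohort sizes, frozen from ``calibrate_cohort_sizes`` with the
#: default configuration (expected total ~582 cases, roughly equal per
#: cohort to support frequency matching).
_DEFAULT_COHORT_SIZES = (115_159, 62_823, 110_834, 223_423, 555_243)


def hr_at(u, baseline: float = 0.25, step: float = 1.35, interval: float = 5.0,
          rounding: int | None = None):
    """Vaccine hazard ratio at ``u`` years since exposure.

    ``baseline * step ** floor(u / interval)``: 0.25 up to 5 years after
    vaccination, then +35% every further 5 years — 0.25, 0.3375, 0.4556,
    0.6151, 0.8304..., i.e. the bands round to 0.25, 0.34, 0.46, 0.62,
    0.83.  With ``rounding`` the per-band ratio is rounded to that many
    decimals, which is how the published schedule states (and uses) it.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ConfigurationError("time since exposure must be >= 0")
    out = baseline * step ** np.floor(u / interval)
    if rounding is not None:
        out = np.round(out, rounding)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of the data-generating process.

    Attributes
    ----------
    birth_cohort_bounds
        Six increasing calendar times bounding the five contiguous birth
        cohorts (default: equal widths over [1984, 2012)).
    cohort_sizes
        Persons per birth cohort (default frozen from calibration to ~582
        expected cases, spread roughly equally over cohorts).
    exposure_prevalence
        Vaccination uptake per cohort.
    age_rate_bounds, age_rates
        Piecewise-constant incidence: rates (per person-year) on the age
        bands between consecutive bounds; ages beyond the last bound keep
        the final rate.
    hr_baseline, hr_step, hr_interval
        The waning-efficacy hazard-ratio schedule (see :func:`hr_at`).
    truncation_time
        Calendar time from which events are observable (left truncation).
    censoring_time
        End of follow-up ("end of 2013" = 2014.0).
    case_age_max
        Cases must have their event strictly below this age (19 or under).
    vaccination_age
        Age at vaccination: a float (default 0: at birth, so age equals
        time since exposure) or a ``(low, high)`` tuple for uniform
        vaccination ages, used to exercise genuinely time-varying exposure.
    hr_rounding
        Decimals to which each band's hazard ratio is rounded before use
        (default 2, the schedule as published: 0.25, 0.34, 0.46, 0.62,
        0.83); ``None`` uses the unrounded compound rule.
    """

    birth_cohort_bounds: tuple = (1984.0, 1989.6, 1995.2, 2000.8, 2006.4, 2012.0)
    cohort_sizes: tuple = _DEFAULT_COHORT_SIZES
    exposure_prevalence: tuple = (0.60, 0.60, 0.80, 0.90, 0.90)
    age_rate_bounds: tuple = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    age_rates: tuple = (13e-5, 14e-5, 16e-5, 36e-5, 40e-5, 45e-5)
    hr_baseline: float = 0.25
    hr_step: float = 1.35
    hr_interval: float = 5.0
    truncation_time: float = 2003.0
    censoring_time: float = 2014.0
    case_age_max: float = 20.0
    vaccination_age: object = 0.0
    hr_rounding: int | None = 2

    def __post_init__(self):
        b = self.birth_cohort_bounds
        if len(b) != len(self.cohort_sizes) + 1 or any(x >= y for x, y in zip(b, b[1:])):
            raise ConfigurationError("cohort bounds must be increasing with one size per interval")
        if len(self.exposure_prevalence) != len(self.cohort_sizes):
            raise ConfigurationError("one exposure prevalence per cohort required")
        if any(not 0 <= p <= 1 for p in self.exposure_prevalence):
            raise ConfigurationError("exposure prevalences must lie in [0, 1]")
        if len(self.age_rates) != len(self.age_rate_bounds) - 1:
            raise ConfigurationError("one rate per age band required")
        if any(r <= 0 for r in self.age_rates):
            raise ConfigurationError("incidence rates must be positive")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)

    def hr_at(self, u):
        """Hazard ratio at ``u`` years since exposure under this schedule."""
        return hr_at(u, self.hr_baseline, self.hr_step, self.hr_interval,
                     self.hr_rounding)

    def rate_at(self, age):
        """Baseline incidence (per person-year) at the given age(s)."""
        age = np.asarray(age, dtype=float)
        idx = np.clip(np.searchsorted(self.age_rate_bounds, age, side="right") - 1,
                      0, len(self.age_rates) - 1)
        return np.asarray(self.age_rates)[idx]

    def with_sizes(self, sizes) -> "SimulationConfig":
        return replace(self, cohort_sizes=tuple(int(s) for s in sizes))


# ---------------------------------------------------------------------------
# piecewise-exponential event-age sampling

_KNOT_MAX_AGE = 200.0  # cumulative hazards are astronomically large well before this


def _knots(config: SimulationConfig, vacc_age: float) -> np.ndarray:
    base = np.arange(0.0, _KNOT_MAX_AGE, config.hr_interval)
    k = np.union1d(np.union1d(base, np.asarray(config.age_rate_bounds)),
                   vacc_age + base[base + vacc_age < _KNOT_MAX_AGE])
    return k[k < _KNOT_MAX_AGE]


def _hazard_on_knots(config: SimulationConfig, knots: np.ndarray, exposed: bool,
                     vacc_age: float) -> np.ndarray:
    """Hazard on each inter-knot interval (evaluated at the left knot)."""
    h = config.rate_at(knots).astype(float)
    if exposed:
        after = knots >= vacc_age
        h[after] *= config.hr_at(knots[after] - vacc_age)
    return h


def _invert_cum_hazard(E: np.ndarray, knots: np.ndarray, haz: np.ndarray) -> np.ndarray:
    """Event ages solving cumhaz(age) = E for a piecewise-constant hazard.

    Beyond the last knot the final hazard is extended indefinitely, so the
    inversion is total (rates are strictly positive).
    """
    widths = np.diff(knots)
    cum = np.concatenate([[0.0], np.cumsum(haz[:-1] * widths)])
    idx = np.clip(np.searchsorted(cum, E, side="right") - 1, 0, len(knots) - 1)
    return knots[idx] + (E - cum[idx]) / haz[idx]


def simulate_cohort(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Generate a full cohort with true (possibly unobserved) event ages.

    Returns one row per person: ``cohort`` (1-based), ``birth`` date,
    ``exposure``, ``vaccination_age``, ``event_age`` (the latent
    piecewise-exponential event age), ``censor_age`` (age at the end of
    follow-up) and ``event_observed`` (event before censoring).
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(config.birth_cohort_bounds)
    parts = []
    for b, (n, prev) in enumerate(zip(config.cohort_sizes, config.exposure_prevalence)):
        birth = rng.uniform(bounds[b], bounds[b + 1], size=n)
        exposed = rng.random(n) < prev
        if isinstance(config.vaccination_age, (tuple, list)):
            lo, hi = config.vaccination_age
            vacc = rng.uniform(lo, hi, size=n)
        else:
            vacc = np.full(n, float(config.vaccination_age))
        vacc[~exposed] = np.nan
        E = rng.exponential(size=n)
        event_age = np.empty(n)
        # unexposed: one shared hazard
        k0 = _knots(config, 0.0)
        event_age[~exposed] = _invert_cum_hazard(
            E[~exposed], k0, _hazard_on_knots(config, k0, False, 0.0))
        # exposed: group by vaccination age (a single value in the default
        # at-birth scenario; per-person knots otherwise)
        if exposed.any():
            vexp = vacc[exposed]
            out = np.empty(vexp.size)
            for va in np.unique(vexp):
                sel = vexp == va
                k = _knots(config, va)
                out[sel] = _invert_cum_hazard(
                    E[exposed][sel], k, _hazard_on_knots(config, k, True, va))
            event_age[exposed] = out
        parts.append(pd.DataFrame({
            "cohort": b + 1,
            "birth": birth,
            "exposure": exposed.astype(int),
            "vaccination_age": vacc,
            "event_age": event_age,
        }))
    cohort = pd.concat(parts, ignore_index=True)
    cohort["censor_age"] = config.censoring_time - cohort["birth"]
    cohort["event_observed"] = cohort["event_age"] < cohort["censor_age"]
    return cohort


def apply_study_window(cohort: pd.DataFrame, config: SimulationConfig):
    """Apply left truncation, the censoring date and the case age cap.

    Returns ``(cases, pool)`` in the canonical subject schema.  Cases are
    events with calendar date in [truncation, censoring) and event age below
    the cap; persons whose event falls outside the window or above the cap
    are excluded from both groups.  The control pool is everyone event-free
    at the censoring date, with entry time max(0, age at truncation) and
    index time equal to their age at the censoring date.
    """
    birth = cohort["birth"].to_numpy()
    event_date = birth + cohort["event_age"].to_numpy()
    observed = cohort["event_observed"].to_numpy()
    entry = np.clip(config.truncation_time - birth, 0.0, None)
    is_case = (observed
               & (event_date >= config.truncation_time)
               & (cohort["event_age"].to_numpy() < config.case_age_max)
               & (cohort["event_age"].to_numpy() > entry))

    def _as_subjects(mask, case_flag, index_time):
        sub = cohort.loc[mask]
        return pd.DataFrame({
            "id": sub.index.to_numpy(),
            "is_case": case_flag,
            "entry_time": entry[mask],
            "index_time": index_time[mask],
            "exposure": sub["exposure"].to_numpy(),
            "exposure_time": sub["vaccination_age"].to_numpy(),
            "stratum": sub["cohort"].to_numpy(),
        })

    cases = _as_subjects(is_case, 1, cohort["event_age"].to_numpy())
    pool = _as_subjects(~observed, 0, cohort["censor_age"].to_numpy())
    return cases, pool


def sample_case_control(cases: pd.DataFrame, pool: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Frequency-matched sampling: per birth cohort, draw as many controls
    (simple random sample without replacement) as there are cases."""
    rng = np.random.default_rng(seed)
    picks = []
    case_counts = cases["stratum"].value_counts()
    for stratum, m in case_counts.sort_index().items():
        avail = pool.index[pool["stratum"] == stratum]
        if avail.size < m:
            raise SimulationError(
                f"birth cohort {stratum}: control pool ({avail.size}) smaller "
                f"than the case count ({m})"
            )
        picks.append(rng.choice(avail.to_numpy(), size=m, replace=False))
    controls = pool.loc[np.concatenate(picks)] if picks else pool.iloc[:0]
    out = pd.concat([cases, controls], ignore_index=True)
    return validate_subjects(out)


def simulate_case_control(config: SimulationConfig | None = None, seed=None):
    """Full pipeline: cohort -> study window -> frequency-matched sample.

    Returns ``(subjects, truth)`` where ``truth`` records the generating
    log hazard-ratio schedule and realised counts.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(config, rng)
    cases, pool = apply_study_window(cohort, config)
    if cases.empty:
        raise SimulationError("simulation produced no cases inside the study window")
    subjects = sample_case_control(cases, pool, rng)
    grid_lo = np.arange(0.0, config.case_age_max, config.hr_interval)
    truth = {
        "hr_schedule": {f"{lo:g}": float(config.hr_at(lo)) for lo in grid_lo},
        "log_hr_schedule": {f"{lo:g}": float(np.log(config.hr_at(lo))) for lo in grid_lo},
        "n_cases": int(cases.shape[0]),
        "n_controls": int(subjects.shape[0] - cases.shape[0]),
        "cases_per_cohort": cases["stratum"].value_counts().sort_index().to_dict(),
    }
    return subjects, truth


def calibrate_cohort_sizes(config: SimulationConfig | None = None,
                           target_cases: float = 582.0, reps: int = 30,
                           seed: int = 0, rounds: int = 3,
                           tol: float = 0.02) -> np.ndarray:
    """Scale cohort sizes so the expected total case count hits a target.

    Pilot cohorts are simulated ``reps`` times per round; each cohort's size
    is rescaled towards an equal share of ``target_cases`` (case counts are
    linear in cohort size in this rare-event regime, so a couple of rounds
    suffice).  Deterministic given ``seed``.
    """
    if target_cases <= 0:
        raise ConfigurationError("target_cases must be positive")
    config = config or SimulationConfig()
    sizes = np.asarray(config.cohort_sizes, dtype=float)
    rng = np.random.default_rng(seed)
    per_cohort_target = target_cases / config.n_cohorts
    mean_counts = None
    for _ in range(rounds):
        cfg = config.with_sizes(np.maximum(np.round(sizes), 100))
        counts = np.zeros(config.n_cohorts)
        for _ in range(reps):
            cohort = simulate_cohort(cfg, rng)
            cases, _ = apply_study_window(cohort, cfg)
            counts += np.bincount(cases["stratum"].to_numpy() - 1,
                                  minlength=config.n_cohorts)
        mean_counts = counts / reps
        if np.any(mean_counts == 0):
            raise SimulationError(
                "a pilot cohort produced no cases; target is infeasible at these sizes"
            )
        sizes = np.array(cfg.cohort_sizes) * per_cohort_target / mean_counts
        if abs(mean_counts.sum() - target_cases) <= tol * target_cases and np.allclose(
                mean_counts, per_cohort_target, rtol=0.05):
            break
    return np.round(sizes).astype(int)
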