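"""Synthetic cohort generator.

Emulates the structure of a two-cohort longitudinal women's-health panel
with registry-linked deaths: a latent monthly disability/recovery/mortality
process per individual, scheduled survey waves (3-yearly, optionally
six-monthly late in follow-up) with jittered interview dates and wave
non-response, baseline dichotomous covariates drawn at configured
prevalences, and exactly dated death months.  Every downstream stage of the
package is testable against data from this module.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .chain import _rows_from_logits
from .panel import (STATE_DEAD, UNKNOWN, IndividualRecord, PanelDataset,
                    WaveObservation, age_in_months, month_index)
from .params import COVARIATES, TransitionParams

__all__ = [
    "SimulationConfig", "LatentPath", "default_true_params", "preset",
    "generate_cohort", "simulate_individual_path", "observe_panel",
]

#: baseline covariate prevalences of the two emulated cohorts
PRESET_PREVALENCES = {
    "cohort1921": {"education": 0.291, "obese": 0.134,
                   "smoker": 0.365, "exercise": 0.847},
    "cohort1946": {"education": 0.503, "obese": 0.191,
                   "smoker": 0.460, "exercise": 0.883},
}

# 6 three-yearly waves 1996-2011, then ten six-monthly waves to 2016
_OFFSETS_1921 = tuple(range(0, 181, 36)) + tuple(range(186, 241, 6))
# baseline 1996, first follow-up 1998, then three-yearly to 2016 (8 waves)
_OFFSETS_1946 = (0, 24) + tuple(range(60, 241, 36))


def default_true_params(covariates: Sequence[str] = COVARIATES,
                        age_center: float = 70.0) -> TransitionParams:
    """Plausible monthly transition hazards for an older female cohort.

    Intercepts are logits of one-month probabilities at ``age_center``;
    slopes are per year of age (mortality roughly doubling every 7-8
    years); covariate effects follow the expected directions (obesity
    mainly on disability onset, smoking mainly on mortality, exercise
    protective, education favourable).  Values are read off general
    female life-table and disability-incidence magnitudes.
    """
    full = {
        #             a        b      edu    obese  smoker exercise
        "free->disabled":  (-6.50, 0.090, -0.30, 0.79, 0.35, -0.50),
        "free->dead":      (-7.10, 0.095, -0.20, 0.10, 0.59, -0.45),
        "disabled->free":  (-4.80, -0.030, 0.20, -0.35, -0.15, 0.30),
        "disabled->dead":  (-5.60, 0.085, -0.10, 0.15, 0.30, -0.25),
    }
    order = dict(zip(COVARIATES, range(4)))
    rows = list(full.values())
    intercepts = [r[0] for r in rows]
    slopes = [r[1] for r in rows]
    coefs = [[r[2 + order[c]] for c in covariates] for r in rows]
    return TransitionParams(
        intercepts=np.array(intercepts), age_slopes=np.array(slopes),
        cov_coefs=np.array(coefs).reshape(4, len(covariates)),
        covariates=tuple(covariates), age_center=age_center,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    cohort_label: str
    n_individuals: int
    birth_year_range: tuple[int, int]
    baseline_year: int
    wave_offsets_months: tuple[int, ...]
    covariate_prevalences: Mapping[str, float]
    true_params: TransitionParams
    wave_response_prob: float = 0.95
    interview_jitter_days: int = 45
    record_nonresponse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        offs = tuple(self.wave_offsets_months)
        if not offs:
            raise ValueError("wave schedule must be nonempty")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("wave offsets must be strictly increasing")
        for name, p in dict(self.covariate_prevalences).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]: {p}")
        if not 0.0 <= self.wave_response_prob <= 1.0:
            raise ValueError("wave_response_prob outside [0, 1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be (lo, hi) with lo <= hi")
        object.__setattr__(self, "wave_offsets_months", offs)
        object.__setattr__(self, "covariate_prevalences",
                           dict(self.covariate_prevalences))
        for c in self.true_params.covariates:
            if c not in self.covariate_prevalences:
                raise ValueError(f"no prevalence configured for covariate {c!r}")


def preset(name: str, n_individuals: int = 2000, seed: int = 0,
           **overrides) -> SimulationConfig:
    """Bundled study conditions: ``"cohort1921"`` (baseline age 70-75,
    3-yearly then six-monthly waves) or ``"cohort1946"`` (baseline age
    45-50, 3-yearly waves)."""
    if name == "cohort1921":
        cfg = SimulationConfig(
            cohort_label="1921-26", n_individuals=n_individuals,
            birth_year_range=(1921, 1926), baseline_year=1996,
            wave_offsets_months=_OFFSETS_1921,
            covariate_prevalences=PRESET_PREVALENCES["cohort1921"],
            true_params=default_true_params(), seed=seed)
    elif name == "cohort1946":
        cfg = SimulationConfig(
            cohort_label="1946-51", n_individuals=n_individuals,
            birth_year_range=(1946, 1951), baseline_year=1996,
            wave_offsets_months=_OFFSETS_1946,
            covariate_prevalences=PRESET_PREVALENCES["cohort1946"],
            true_params=default_true_params(), seed=seed)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class LatentPath:
    """Latent step-resolution state sequence for one individual.

    ``states[k]`` is the state at age ``start_age_months + k`` months (or
    the corresponding step for non-monthly chains).  Death is absorbing;
    the sequence is truncated one step after absorption.
    """

    individual_id: str
    start_age_months: int
    states: np.ndarray

    @property
    def death_age_months(self) -> int | None:
        """Age month during which death occurred (the step whose transition
        entered the absorbing state), or None if alive at the horizon."""
        dead = np.flatnonzero(self.states == STATE_DEAD)
        if dead.size == 0:
            return None
        return self.start_age_months + int(dead[0]) - 1

    def state_at(self, age_months: int) -> int:
        k = age_months - self.start_age_months
        if k < 0:
            raise ValueError("age before path start")
        if k >= len(self.states):
            k = len(self.states) - 1  # absorbed paths are truncated
            if self.states[k] != STATE_DEAD:
                raise ValueError("age beyond simulated horizon")
        return int(self.states[k])


def _simulate_state_matrix(t0: np.ndarray, t_end: int, x: np.ndarray,
                           params: TransitionParams,
                           rng: np.random.Generator) -> np.ndarray:
    """Simulate states for all individuals on a common step grid.

    Returns an int8 matrix S with S[n, t - t_min] = state of individual n
    at step-age t (UNKNOWN before the individual's start).
    """
    t_min = int(t0.min())
    T = t_end - t_min
    if T < 1:
        raise ValueError("horizon must exceed every start age")
    groups, gidx = np.unique(x, axis=0, return_inverse=True)
    spy = params.steps_per_year
    ages = (t_min + np.arange(T)) / spy
    # rows[t, g, origin, dest]
    eta = np.stack([params.logits(ages, g) for g in groups], axis=1)
    rows = _rows_from_logits(eta)
    cum = np.cumsum(rows, axis=-1)
    n = len(t0)
    S = np.full((n, T + 1), UNKNOWN, dtype=np.int8)
    state = np.zeros(n, dtype=np.int64)
    for k in range(T):
        t = t_min + k
        starting = t0 == t
        S[starting, k] = 0
        active = (t0 <= t) & (state != STATE_DEAD)
        u = rng.random(n)  # fixed-length draw keeps streams reproducible
        idx = np.flatnonzero(active)
        if idx.size:
            c = cum[k, gidx[idx], state[idx], :]
            nxt = (u[idx, None] >= c).sum(axis=1)
            state[idx] = nxt
            S[idx, k + 1] = nxt
        S[np.flatnonzero((t0 <= t) & ~active), k + 1] = STATE_DEAD
    return S


def simulate_individual_path(start_age: float, profile: Mapping[str, int] | None,
                             params: TransitionParams, horizon_age: float,
                             rng: np.random.Generator,
                             individual_id: str = "sim") -> LatentPath:
    """Simulate one latent path from ``start_age`` (state 0) to death or
    ``horizon_age``, stepping at the chain's resolution."""
    if start_age >= horizon_age:
        raise ValueError("start_age must be below horizon_age")
    spy = params.steps_per_year
    t0 = int(round(start_age * spy))
    t_end = int(round(horizon_age * spy))
    x = params.profile_vector(profile)
    S = _simulate_state_matrix(np.array([t0]), t_end, x[None, :], params, rng)
    states = S[0, S[0] != UNKNOWN].astype(np.int8)
    dead = np.flatnonzero(states == STATE_DEAD)
    if dead.size:
        states = states[: int(dead[0]) + 1]
    return LatentPath(individual_id, t0, states)


def simulate_expectancies(params: TransitionParams,
                          profile: Mapping[str, int] | None, age: float,
                          n_paths: int, rng: np.random.Generator,
                          closing_age: float = 115.0) -> dict:
    """Monte-Carlo expectancies: mean years per state over simulated paths.

    Each path starts disability-free at ``age`` and is scored with the
    same trapezoid time-integration as the matrix-product estimator (half
    weight on the first and last step), so the two agree in expectation
    and differ only by Monte-Carlo error.  Returns means and standard
    errors for TLE / DFLE / DLE.
    """
    spy = params.steps_per_year
    t0 = int(round(age * spy))
    t_end = int(round(closing_age * spy))
    x = np.tile(params.profile_vector(profile), (n_paths, 1))
    S = _simulate_state_matrix(np.full(n_paths, t0), t_end, x, params, rng)
    w = np.ones(S.shape[1])
    w[0] = w[-1] = 0.5
    dfle = ((S == 0) * w).sum(axis=1) / spy
    dle = ((S == 1) * w).sum(axis=1) / spy
    tle = dfle + dle
    out = {}
    for name, v in (("TLE", tle), ("DFLE", dfle), ("DLE", dle)):
        out[name] = float(v.mean())
        out[f"{name}_mc_se"] = float(v.std(ddof=1) / np.sqrt(n_paths))
    return out


def _add_months(year: int, month: int, offset: int) -> tuple[int, int]:
    m = month_index(year, month) + offset
    return m // 12, m % 12 + 1


def observe_panel(paths: Sequence[LatentPath],
                  wave_dates: Sequence[Sequence[dt.date]],
                  response_prob: float,
                  rng: np.random.Generator,
                  births: Sequence[tuple[int, int]],
                  covariates: Sequence[Mapping[str, int]] | None = None,
                  record_nonresponse: bool = False) -> PanelDataset:
    """Observe latent paths at scheduled interview dates.

    The first (baseline) wave is always observed; at later waves, alive
    individuals respond with probability ``response_prob``.  Non-responded
    waves are omitted by default (set ``record_nonresponse`` to keep them
    as unknown-state records).  Death months are copied exactly from the
    path, emulating registry linkage, regardless of response; no wave
    record is emitted after the death month.
    """
    individuals = []
    for k, path in enumerate(paths):
        by, bm = births[k]
        covs = dict(covariates[k]) if covariates is not None else {}
        d = path.death_age_months
        waves = []
        for w, date in enumerate(wave_dates[k]):
            t = age_in_months(by, bm, date)
            if d is not None and t > d:
                break
            responded = w == 0 or rng.random() < response_prob
            if responded:
                waves.append(WaveObservation(date=date, state=path.state_at(t)))
            elif record_nonresponse:
                waves.append(WaveObservation(date=date, state=UNKNOWN))
        rec = IndividualRecord(
            id=path.individual_id, birth_month=bm, birth_year=by,
            education=covs.get("education"), obese=covs.get("obese"),
            smoker=covs.get("smoker"), exercise=covs.get("exercise"),
            waves=waves)
        if d is not None:
            dy, dm = _add_months(by, bm, d)
            rec.death_year, rec.death_month = dy, dm
        individuals.append(rec)
    dataset = PanelDataset(individuals=individuals)
    dataset.validate()
    return dataset


def generate_cohort(config: SimulationConfig) -> PanelDataset:
    """Generate a full synthetic panel under ``config``.

    Birth months are uniform within the configured year range, baseline
    covariates independent Bernoulli draws at the configured prevalences,
    and every individual starts disability-free at their baseline
    interview.  Fully reproducible from ``config.seed``.
    """
    params = config.true_params
    if params.steps_per_year != 12:
        raise ValueError("the cohort generator runs on a monthly latent grid")
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    y0, y1 = config.birth_year_range
    birth_year = rng.integers(y0, y1 + 1, size=n)
    birth_month = rng.integers(1, 13, size=n)
    cov_names = tuple(config.covariate_prevalences)
    cov_draws = {c: (rng.random(n) < config.covariate_prevalences[c]).astype(int)
                 for c in cov_names}

    jit = config.interview_jitter_days
    offsets = np.asarray(config.wave_offsets_months)
    base = dt.date(config.baseline_year, 6, 15)
    jitter = (rng.integers(-jit, jit + 1, size=(n, len(offsets)))
              if jit else np.zeros((n, len(offsets)), dtype=int))
    wave_dates: list[list[dt.date]] = []
    for i in range(n):
        dates = []
        for w, off in enumerate(offsets):
            y, m = _add_months(base.year, base.month, int(off))
            day = min(base.day, calendar.monthrange(y, m)[1])
            dates.append(dt.date(y, m, day) + dt.timedelta(days=int(jitter[i, w])))
        wave_dates.append(dates)

    t0 = np.array([age_in_months(int(birth_year[i]), int(birth_month[i]),
                                 wave_dates[i][0]) for i in range(n)])
    t_end = 1 + max(age_in_months(int(birth_year[i]), int(birth_month[i]),
                                  wave_dates[i][-1]) for i in range(n))
    x = np.column_stack([cov_draws[c] for c in params.covariates]) \
        if params.covariates else np.zeros((n, 0))
    S = _simulate_state_matrix(t0, t_end, x, params, rng)
    # registry linkage ends with the individual's own follow-up calendar:
    # deaths after the last interview date are censored (individual appears
    # alive at end of study), so the death window matches the study window.
    censor = np.array([age_in_months(int(birth_year[i]), int(birth_month[i]),
                                     wave_dates[i][-1]) for i in range(n)])
    paths = []
    for i in range(n):
        states = S[i, S[i] != UNKNOWN].astype(np.int8)
        dead = np.flatnonzero(states == STATE_DEAD)
        if dead.size:
            d = int(t0[i]) + int(dead[0]) - 1  # month the transition occurred
            if d > censor[i]:
                states = states[: censor[i] - int(t0[i]) + 1]
            else:
                states = states[: int(dead[0]) + 1]
        paths.append(LatentPath(f"{config.cohort_label}-{i:06d}",
                                int(t0[i]), states))
    covs = [{c: int(cov_draws[c][i]) for c in cov_names} for i in range(n)]
    births = [(int(birth_year[i]), int(birth_month[i])) for i in range(n)]
    return observe_panel(paths, wave_dates, config.wave_response_prob, rng,
                         births, covs,
                         record_nonresponse=config.record_nonresponse)
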