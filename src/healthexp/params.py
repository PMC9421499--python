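"""Parameterisation of the monthly transition hazards.

The process is an illness–death chain with states

    0  disability-free
    1  disabled
    2  dead (absorbing)

Within each one-month step, the probabilities of leaving the current
transient state are multinomial-logistic in exact age (years) and a set of
dichotomous covariates, with "stay in the current state" as the reference
category.  Four transitions carry parameters: 0→1 (disability onset),
0→2 (death while free), 1→0 (recovery), 1→2 (death while disabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: allowed transitions (origin, destination), fixed ordering used everywhere
TRANSITIONS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 0), (1, 2))

TRANSITION_LABELS: tuple[str, ...] = (
    "free->disabled",
    "free->dead",
    "disabled->free",
    "disabled->dead",
)

#: canonical covariate names of the analysis
COVARIATES: tuple[str, ...] = ("education", "obese", "smoker", "exercise")


@dataclass(frozen=True)
class TransitionParams:
    """Coefficients of the multinomial-logit one-month transition model.

    For transition r = (i, j) the linear predictor at exact age ``a`` (years)
    and covariate vector ``x`` is

        eta_r = intercepts[r] + age_slopes[r] * (a - age_center)
                + sum_k cov_coefs[r, k] * x[k]

    and the one-month probabilities from origin i are the softmax of the
    destination logits with eta = 0 for staying.  ``age_center`` defaults to
    0 so the stored coefficients read as plain intercept + slope * age.

    Parameters
    ----------
    intercepts, age_slopes : array-like, shape (4,)
        One entry per transition in :data:`TRANSITIONS` order.
    cov_coefs : array-like, shape (4, k)
        One column per name in ``covariates``.
    covariates : sequence of str
        Names of the active dichotomous covariates (may be empty).
    steps_per_year : int
        Number of elementary steps per year (h = 1 / steps_per_year years).
        12 (monthly) is the default and the resolution of all dated data.
    age_center : float
        Age (years) subtracted before applying ``age_slopes``.
    """

    intercepts: np.ndarray
    age_slopes: np.ndarray
    cov_coefs: np.ndarray = field(default_factory=lambda: np.zeros((4, 0)))
    covariates: tuple[str, ...] = ()
    steps_per_year: int = 12
    age_center: float = 0.0

    def __post_init__(self) -> None:
        inter = np.asarray(self.intercepts, dtype=float).reshape(4)
        slope = np.asarray(self.age_slopes, dtype=float).reshape(4)
        k = len(self.covariates)
        coefs = np.asarray(self.cov_coefs, dtype=float).reshape(4, k)
        for name, arr in (("intercepts", inter), ("age_slopes", slope),
                          ("cov_coefs", coefs)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite value in {name}")
        if not (isinstance(self.steps_per_year, (int, np.integer))
                and 1 <= self.steps_per_year <= 366):
            raise ValueError("steps_per_year must be an integer in [1, 366]")
        object.__setattr__(self, "intercepts", inter)
        object.__setattr__(self, "age_slopes", slope)
        object.__setattr__(self, "cov_coefs", coefs)
        object.__setattr__(self, "covariates", tuple(self.covariates))

    # -- vector round trip (optimizer order: per transition, then per column)

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def n_params(self) -> int:
        return 4 * (2 + self.n_covariates)

    def to_vector(self) -> np.ndarray:
        """Flatten to shape (4 * (2 + k),): rows are transitions, columns are
        (intercept, age slope, covariate coefficients...)."""
        return np.column_stack(
            [self.intercepts, self.age_slopes, self.cov_coefs]
        ).ravel()

    @classmethod
    def from_vector(
        cls,
        theta: np.ndarray,
        covariates: Sequence[str] = (),
        steps_per_year: int = 12,
        age_center: float = 0.0,
    ) -> "TransitionParams":
        k = len(covariates)
        mat = np.asarray(theta, dtype=float).reshape(4, 2 + k)
        return cls(
            intercepts=mat[:, 0],
            age_slopes=mat[:, 1],
            cov_coefs=mat[:, 2:],
            covariates=tuple(covariates),
            steps_per_year=steps_per_year,
            age_center=age_center,
        )

    def with_age_center(self, center: float) -> "TransitionParams":
        """Re-express with a different age centering (same model)."""
        shift = center - self.age_center
        return replace(self, intercepts=self.intercepts + self.age_slopes * shift,
                       age_center=center)

    def rescaled(self, steps_per_year: int) -> "TransitionParams":
        """Re-express the hazards on a finer (or coarser) step grid.

        Per-step exit probabilities of a rare-event chain scale with the step
        length, so the destination logits shift by log(h_new / h_old); this is
        the usual embedded-chain approximation and is exact in the
        continuous-time limit.
        """
        if steps_per_year == self.steps_per_year:
            return self
        shift = float(np.log(self.steps_per_year / steps_per_year))
        return replace(self, intercepts=self.intercepts + shift,
                       steps_per_year=steps_per_year)

    # -- linear predictors

    def profile_vector(self, profile: Mapping[str, int] | None) -> np.ndarray:
        """Covariate vector for ``profile`` in this object's covariate order.

        Every active covariate must be present with a 0/1 value; extra keys
        are ignored.
        """
        profile = dict(profile or {})
        x = np.empty(self.n_covariates)
        for k, name in enumerate(self.covariates):
            if name not in profile:
                raise ValueError(f"profile is missing covariate {name!r}")
            v = profile[name]
            if v not in (0, 1):
                raise ValueError(f"covariate {name!r} must be 0 or 1, got {v!r}")
            x[k] = v
        return x

    def logits(self, age: float | np.ndarray,
               x: np.ndarray) -> np.ndarray:
        """Destination logits eta_r, shape (..., 4), for age(s) in years."""
        a = np.asarray(age, dtype=float)
        return (self.intercepts + self.cov_coefs @ x
                + np.multiply.outer(a - self.age_center, self.age_slopes))
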