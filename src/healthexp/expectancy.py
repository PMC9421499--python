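"""Health expectancies from fitted transition models.

Total life expectancy (TLE), disability-free life expectancy (DFLE) and
life with disability (DLE) at an exact age are time-integrals of the state
occupancy probabilities obtained by iterating the one-step transition
matrices to a closing age.  TLE = DFLE + DLE holds by construction.
Uncertainty comes from a parametric bootstrap over the estimated
coefficient distribution (default) or from the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .chain import _rows_from_logits
from .model import Z95
from .params import TransitionParams

__all__ = ["ExpectancyEstimate", "OccupancyCurve", "occupancy_curve",
           "state_expectancies", "expectancy_uncertainty"]

QUANTITIES = ("TLE", "DFLE", "DLE")

_WEIGHTINGS = ("disability-free", "disabled", "prevalence")


@dataclass
class OccupancyCurve:
    """State occupancy probabilities from age ``age`` to the closing age."""

    age: float
    weighting: str
    ages: np.ndarray        # (T+1,), years
    occupancy: np.ndarray   # (T+1, 3)

    @property
    def residual_transient_mass(self) -> float:
        return float(self.occupancy[-1, :2].sum())


@dataclass
class ExpectancyEstimate:
    """TLE/DFLE/DLE at one age and profile, optionally with SEs and CIs."""

    age: float
    profile: dict
    weighting: str
    tle: float
    dfle: float
    dle: float
    closing_age: float
    residual_transient_mass: float
    se: dict | None = None
    ci: dict | None = None
    method: str | None = None

    def value(self, quantity: str) -> float:
        return {"TLE": self.tle, "DFLE": self.dfle, "DLE": self.dle}[quantity]


def _batch_mats(thetas: np.ndarray, params: TransitionParams,
                x: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Full 3x3 step matrices, shape (B, T, 3, 3), for B parameter draws.

    ``thetas`` are vectors in the parameterisation of ``params`` (same
    covariates, steps, centering).
    """
    B = thetas.reshape(len(thetas), 4, 2 + len(params.covariates))
    inter = B[:, :, 0] + B[:, :, 2:] @ x          # (B, 4)
    slope = B[:, :, 1]                            # (B, 4)
    ac = ages - params.age_center                 # (T,)
    eta = inter[:, None, :] + slope[:, None, :] * ac[None, :, None]
    rows = _rows_from_logits(eta)                 # (B, T, 2, 3)
    out = np.zeros(rows.shape[:2] + (3, 3))
    out[..., :2, :] = rows
    out[..., 2, 2] = 1.0
    return out


def _initial_distribution(mats_anchor: np.ndarray, weighting: str) -> np.ndarray:
    """Initial distribution(s), shape (B, 3), for each draw.

    ``mats_anchor`` holds the step matrices from the anchor age up to the
    target age (empty for the state-conditional modes).
    """
    Bn = mats_anchor.shape[0]
    if weighting == "disability-free":
        d = np.tile([1.0, 0.0, 0.0], (Bn, 1))
    elif weighting == "disabled":
        d = np.tile([0.0, 1.0, 0.0], (Bn, 1))
    elif weighting == "prevalence":
        d = np.tile([1.0, 0.0, 0.0], (Bn, 1))
        for t in range(mats_anchor.shape[1]):
            d = np.einsum("bi,bij->bj", d, mats_anchor[:, t])
        d[:, 2] = 0.0  # condition on being alive at the target age
        d /= d.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown weighting {weighting!r}; "
                         f"expected one of {_WEIGHTINGS}")
    return d


def _batch_expectancies(thetas: np.ndarray, params: TransitionParams,
                        profile: Mapping[str, int], age: float,
                        weighting: str, closing_age: float,
                        anchor_age: float | None,
                        return_curve: bool = False):
    """(B, 3) array of (DFLE, DLE, residual mass) per draw; optionally the
    occupancy curve of the first draw."""
    if age >= closing_age:
        raise ValueError("age must be below closing_age")
    x = params.profile_vector(profile)
    spy = params.steps_per_year
    h = 1.0 / spy
    T = int(round((closing_age - age) * spy))
    ages = age + np.arange(T) / spy
    mats = _batch_mats(thetas, params, x, ages)
    if weighting == "prevalence":
        anchor = max(age - 20.0, 0.0) if anchor_age is None else anchor_age
        if anchor > age:
            raise ValueError("anchor_age must not exceed the target age")
        Ta = int(round((age - anchor) * spy))
        ages_a = anchor + np.arange(Ta) / spy
        mats_a = _batch_mats(thetas, params, x, ages_a)
    else:
        mats_a = np.empty((len(thetas), 0, 3, 3))
    d = _initial_distribution(mats_a, weighting)
    # trapezoid weights: half at both ends of the occupancy grid
    dfle = 0.5 * d[:, 0].copy()
    dle = 0.5 * d[:, 1].copy()
    curve = np.empty((T + 1, 3)) if return_curve else None
    if return_curve:
        curve[0] = d[0]
    for t in range(T):
        d = np.einsum("bi,bij->bj", d, mats[:, t])
        wt = 0.5 if t == T - 1 else 1.0
        dfle += wt * d[:, 0]
        dle += wt * d[:, 1]
        if return_curve:
            curve[t + 1] = d[0]
    out = np.column_stack([dfle * h, dle * h, d[:, 0] + d[:, 1]])
    return (out, curve) if return_curve else out


def occupancy_curve(params: TransitionParams, profile: Mapping[str, int],
                    age: float, weighting: str = "disability-free",
                    closing_age: float = 115.0,
                    anchor_age: float | None = None) -> OccupancyCurve:
    """Monthly state-occupancy probabilities from ``age`` to ``closing_age``.

    The initial distribution is a unit mass on a transient state
    (``"disability-free"`` / ``"disabled"``) or the model-implied state mix
    among survivors at ``age``, obtained by forward iteration from
    ``anchor_age`` (default: 20 years before ``age``).
    """
    theta = params.to_vector()[None, :]
    _, curve = _batch_expectancies(theta, params, profile, age, weighting,
                                   closing_age, anchor_age, return_curve=True)
    spy = params.steps_per_year
    ages = age + np.arange(curve.shape[0]) / spy
    return OccupancyCurve(age=age, weighting=weighting, ages=ages,
                          occupancy=curve)


def state_expectancies(params: TransitionParams, profile: Mapping[str, int],
                       age: float, weighting: str = "disability-free",
                       closing_age: float = 115.0,
                       anchor_age: float | None = None) -> ExpectancyEstimate:
    """Point estimates of TLE, DFLE and DLE at ``age`` (years).

    DFLE (DLE) is the step length times the trapezoid-weighted sum of the
    disability-free (disabled) occupancy probabilities out to the closing
    age; TLE is their sum.  Transient mass left at the closing age (logged
    on the estimate) enters through the half-weighted final point.
    """
    out = _batch_expectancies(params.to_vector()[None, :], params, profile,
                              age, weighting, closing_age, anchor_age)
    dfle, dle, resid = (float(v) for v in out[0])
    return ExpectancyEstimate(
        age=age, profile=dict(profile or {}), weighting=weighting,
        tle=dfle + dle, dfle=dfle, dle=dle, closing_age=closing_age,
        residual_transient_mass=resid)


def _psd_factor(cov: np.ndarray, repair: bool) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    tol = 1e-8 * max(float(vals.max()), 1e-12)
    if vals.min() < -tol and not repair:
        raise ValueError(
            "parameter covariance is not positive semidefinite; pass "
            "repair=True to project onto the nearest PSD matrix (delta "
            "method on the repaired matrix is then flagged)")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def expectancy_uncertainty(results, profile: Mapping[str, int], age: float,
                           weighting: str = "disability-free",
                           method: str = "bootstrap", n_boot: int = 1000,
                           seed: int | None = None,
                           closing_age: float = 115.0,
                           anchor_age: float | None = None,
                           repair: bool = False) -> ExpectancyEstimate:
    """TLE/DFLE/DLE with SEs and 95% CIs from a fitted model.

    ``method="bootstrap"`` (default) draws ``n_boot`` coefficient vectors
    from the normal approximation N(theta, cov), recomputes the
    expectancies for each, and reports the SD as SE with 2.5/97.5
    percentile CIs; ``method="delta"`` propagates a central-difference
    gradient through the covariance and uses normal CIs.  Seeded and
    reproducible.
    """
    params = results.params_centered
    theta = params.to_vector()
    cov = results.cov_params
    if cov is None:
        raise ValueError("fit carries no parameter covariance")
    point = _batch_expectancies(theta[None, :], params, profile, age,
                                weighting, closing_age, anchor_age)[0]
    est = {"DFLE": float(point[0]), "DLE": float(point[1])}
    est["TLE"] = est["DFLE"] + est["DLE"]
    if method == "bootstrap":
        factor = _psd_factor(cov, repair)
        rng = np.random.default_rng(seed)
        draws = theta + rng.standard_normal((n_boot, theta.size)) @ factor.T
        vals = _batch_expectancies(draws, params, profile, age, weighting,
                                   closing_age, anchor_age)
        samples = {"DFLE": vals[:, 0], "DLE": vals[:, 1],
                   "TLE": vals[:, 0] + vals[:, 1]}
        se = {q: float(np.std(samples[q], ddof=1)) for q in QUANTITIES}
        ci = {q: (float(np.percentile(samples[q], 2.5)),
                  float(np.percentile(samples[q], 97.5))) for q in QUANTITIES}
    elif method == "delta":
        _psd_factor(cov, repair)  # validate (or accept repaired) covariance
        grads = _delta_gradients(results, profile, age, weighting,
                                 closing_age, anchor_age)
        se = {}
        ci = {}
        for q in QUANTITIES:
            g = grads[q]
            var = float(g @ cov @ g)
            se[q] = float(np.sqrt(max(var, 0.0)))
            ci[q] = (est[q] - Z95 * se[q], est[q] + Z95 * se[q])
    else:
        raise ValueError(f"unknown uncertainty method {method!r}")
    return ExpectancyEstimate(
        age=age, profile=dict(profile or {}), weighting=weighting,
        tle=est["TLE"], dfle=est["DFLE"], dle=est["DLE"],
        closing_age=closing_age, residual_transient_mass=float(point[2]),
        se=se, ci=ci, method=method)


def _delta_gradients(results, profile, age, weighting="disability-free",
                     closing_age=115.0, anchor_age=None) -> dict:
    """Central-difference gradients of each expectancy w.r.t. the centered
    coefficient vector; returns {quantity: (p,) array}."""
    params = results.params_centered
    theta = params.to_vector()
    p = theta.size
    h = 1e-5 * (1.0 + np.abs(theta))
    pts = np.repeat(theta[None, :], 2 * p, axis=0)
    for i in range(p):
        pts[2 * i, i] += h[i]
        pts[2 * i + 1, i] -= h[i]
    vals = _batch_expectancies(pts, params, profile, age, weighting,
                               closing_age, anchor_age)
    diffs = (vals[0::2] - vals[1::2]) / (2 * h[:, None])  # (p, 3)
    return {"DFLE": diffs[:, 0], "DLE": diffs[:, 1],
            "TLE": diffs[:, 0] + diffs[:, 1]}
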