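"""Maximum-likelihood fitting of the multi-state disability model.

`DisabilityMarkovModel` is built from a :class:`~healthexp.panel.PanelDataset`
(states derived, exclusions applied) and a choice of active dichotomous
covariates; `fit()` maximises the interval-censored likelihood of the
monthly embedded chain and returns a `DisabilityMarkovResults` carrying the
estimates, their covariance, diagnostics, relative-risk ratios and
health-expectancy methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from . import chain
from ._likelihood import build_episodes
from .panel import PanelDataset, age_in_months
from .params import TRANSITION_LABELS, TRANSITIONS, TransitionParams

__all__ = ["DisabilityMarkovModel", "DisabilityMarkovResults", "RrrEstimate",
           "individual_log_likelihood"]

Z95 = 1.959963984540054  # normal 97.5% quantile, used for all 95% intervals


def individual_log_likelihood(record, params: TransitionParams) -> float:
    """Reference (plain NumPy) log-likelihood contribution of one individual.

    Sums log interval probabilities between consecutive known-state waves
    (unknown-state waves only lengthen the interval, marginalising the
    latent state via the matrix product); an exactly dated death adds the
    probability of surviving to the death month times that month's one-step
    death probability, summed over the latent transient state.  A single
    observation with no death contributes 0; a record whose only
    information is a death is rejected.
    """
    profile = {c: record.covariate(c) for c in params.covariates}
    x = params.profile_vector(profile)
    spy = params.steps_per_year
    obs = []
    for wv in record.waves:
        if wv.state in (0, 1):
            t = age_in_months(record.birth_year, record.birth_month, wv.date)
            t = int(round(t * spy / 12))
            if not obs or t > obs[-1][0]:
                obs.append((t, wv.state))
    d = record.death_age_months()
    if d is not None:
        d = int(round(d * spy / 12))
    if not obs:
        if d is not None:
            raise ValueError(
                f"{record.id}: a death with no prior observed state has no "
                "definable likelihood contribution")
        return 0.0
    ll = 0.0
    for (ta, sa), (tb, sb) in zip(obs, obs[1:]):
        ll += np.log(chain.interval_probability(
            sa, ta / spy, sb, tb / spy, profile, params))
    if d is not None:
        tl, sl = obs[-1]
        d = max(d, tl)
        surv = [chain.interval_probability(sl, tl / spy, s, d / spy,
                                           profile, params) for s in (0, 1)]
        death_col = chain.step_transition_matrix(d / spy, profile, params)[:2, 2]
        ll += np.log(float(np.dot(surv, death_col)))
    return float(ll)


@dataclass(frozen=True)
class RrrEstimate:
    """Relative risk ratio of one covariate on one transition."""

    transition: str
    covariate: str
    coef: float
    se: float
    rrr: float
    ci: tuple[float, float]
    p_value: float


class DisabilityMarkovModel:
    """Interval-censored multinomial-logit transition model on a panel.

    Parameters
    ----------
    dataset : PanelDataset
        Panel with derived states.  Individuals must have non-missing
        values for every active covariate.
    covariates : sequence of str
        Active dichotomous covariates (subset of education/obese/smoker/
        exercise); may be empty for a stratified age-only model.
    age_center : float
        Age (years) at which the internal optimisation centers age, for
        conditioning; reported coefficients are de-centered.
    steps_per_year : int
        Elementary step resolution of the embedded chain (12 = monthly).
    """

    def __init__(self, dataset: PanelDataset, covariates: Sequence[str] = (),
                 age_center: float = 70.0, steps_per_year: int = 12):
        self.covariates = tuple(covariates)
        self.age_center = float(age_center)
        self.steps_per_year = int(steps_per_year)
        self.data = build_episodes(dataset, self.covariates, self.steps_per_year)
        self._ages_c = self.data.ages_centered(self.steps_per_year,
                                               self.age_center)
        self.nobs = self.data.n_individuals

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DisabilityMarkovModel":
        from .io import read_panel_csv
        return cls(read_panel_csv(path), **kwargs)

    # ------------------------------------------------------------- likelihood

    def _check_identified(self) -> None:
        c = self.data.counts
        missing = []
        if c["0->1"] == 0:
            missing.append(TRANSITION_LABELS[0])
        if c["1->0"] == 0:
            missing.append(TRANSITION_LABELS[2])
        if c["death_from_0"] + c["death_from_1"] == 0:
            missing.append("(any)->dead")
        if missing:
            raise ValueError(
                "no observed transitions identify: " + ", ".join(missing))

    def _theta_centered(self, params: TransitionParams) -> np.ndarray:
        if tuple(params.covariates) != self.covariates:
            raise ValueError("params covariates do not match the model")
        return params.with_age_center(self.age_center).to_vector()

    def loglike(self, params: TransitionParams) -> float:
        """Total log-likelihood at ``params``."""
        B = self._theta_centered(params).reshape(4, 2 + len(self.covariates))
        ll, _ = self.data.loglike(B, self._ages_c, False)
        return float(ll)

    def score(self, params: TransitionParams) -> np.ndarray:
        """Gradient of the log-likelihood in the centered parameterisation,
        shape (4, 2 + k)."""
        B = self._theta_centered(params).reshape(4, 2 + len(self.covariates))
        _, g = self.data.loglike(B, self._ages_c, True)
        return g

    def _negloglike_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        B = theta.reshape(4, 2 + len(self.covariates))
        ll, g = self.data.loglike(B, self._ages_c, True)
        return -ll, -g.ravel()

    # ------------------------------------------------------------------- fit

    def start_params(self) -> np.ndarray:
        """Crude initial values: aggregate transition frequencies converted
        to logits; age slopes and covariate effects start at 0."""
        c = self.data.counts
        steps = np.zeros(2)
        for t0, tend, i, w in zip(self.data.t0, self.data.tend,
                                  self.data.i0, self.data.w):
            steps[i] += w * max(tend - t0, 1)
        theta = np.zeros((4, 2 + len(self.covariates)))
        events = {0: c["0->1"], 1: c["death_from_0"],
                  2: c["1->0"], 3: c["death_from_1"]}
        for r, (orig, _dest) in enumerate(TRANSITIONS):
            rate = events[r] / max(steps[orig], 1.0)
            theta[r, 0] = np.clip(np.log(max(rate, 1e-6)), -12.0, -1.5)
        return theta.ravel()

    def fit(self, start_params: TransitionParams | np.ndarray | None = None,
            maxiter: int = 500, se: bool = True,
            separation_bound: float = 15.0) -> "DisabilityMarkovResults":
        """Maximise the likelihood by quasi-Newton (L-BFGS-B) iteration.

        Raises if an essential transition is never observed; flags (never
        silently ignores) non-convergence and apparent separation
        (coefficients running to the ``separation_bound`` guard).
        """
        self._check_identified()
        if start_params is None:
            x0 = self.start_params()
        elif isinstance(start_params, TransitionParams):
            x0 = self._theta_centered(start_params)
        else:
            x0 = np.asarray(start_params, dtype=float).ravel()
        scale = max(1.0, self.data.total_weight)
        res = optimize.minimize(
            self._negloglike_grad, x0, jac=True, method="L-BFGS-B",
            options=dict(maxiter=maxiter, maxfun=50 * maxiter,
                         ftol=1e-14, gtol=1e-8 * scale))
        theta = res.x
        nll, grad = self._negloglike_grad(theta)
        gnorm = float(np.max(np.abs(grad)))
        # Newton polish: quasi-Newton line searches stall near the optimum,
        # so refine with full Newton steps until the score is negligible
        H = None
        for _ in range(4):
            if gnorm < 1e-10 * scale:
                break
            H = self._observed_information(theta)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            cand = theta - step
            nll2, grad2 = self._negloglike_grad(cand)
            gnorm2 = float(np.max(np.abs(grad2)))
            if not np.isfinite(nll2) or gnorm2 >= gnorm:
                break  # H stays valid: it was evaluated at the kept theta
            theta, nll, grad, gnorm = cand, nll2, grad2, gnorm2
            H = None  # stale after the accepted step
        converged = bool(res.success) or gnorm < 1e-5 * scale
        separation = bool(np.max(np.abs(theta)) > separation_bound)
        cov = None
        cov_flags = []
        if se:
            if H is None:
                H = self._observed_information(theta)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
                cov_flags.append("singular information matrix (pseudo-inverse)")
            cov = 0.5 * (cov + cov.T)
            eig = np.linalg.eigvalsh(cov)
            if eig.min() < -1e-10 * max(eig.max(), 1.0):
                cov_flags.append("covariance not PSD")
        return DisabilityMarkovResults(
            model=self, theta=theta, cov_params_internal=cov,
            llf=float(-res.fun), converged=converged, grad_norm=gnorm,
            n_iter=int(res.nit), separation_flag=separation,
            cov_flags=tuple(cov_flags), message=str(res.message))

    def _observed_information(self, theta: np.ndarray) -> np.ndarray:
        """Observed information: central differences of the analytic
        gradient of the negative log-likelihood."""
        p = theta.size
        H = np.empty((p, p))
        for i in range(p):
            h = 1e-5 * (1.0 + abs(theta[i]))
            tp = theta.copy()
            tp[i] += h
            _, gp = self._negloglike_grad(tp)
            tp[i] -= 2 * h
            _, gm = self._negloglike_grad(tp)
            H[:, i] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)


class DisabilityMarkovResults:
    """Fitted model: estimates, covariance, diagnostics, derived quantities.

    ``params`` is the de-centered :class:`TransitionParams` (logits read as
    intercept + slope * age in years); ``params_centered`` keeps the
    optimiser's centering, matching ``cov_params`` (the inverse observed
    information in that parameterisation).
    """

    def __init__(self, model, theta, cov_params_internal, llf, converged,
                 grad_norm, n_iter, separation_flag, cov_flags, message):
        self.model = model
        self._theta = np.asarray(theta, dtype=float)
        self.params_centered = TransitionParams.from_vector(
            self._theta, covariates=model.covariates,
            steps_per_year=model.steps_per_year, age_center=model.age_center)
        self.params = self.params_centered.with_age_center(0.0)
        self.cov_params = cov_params_internal
        self.llf = llf
        self.converged = converged
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        self.separation_flag = separation_flag
        self.cov_flags = cov_flags
        self.message = message

    # ------------------------------------------------------------ inference

    @property
    def k_params(self) -> int:
        return self._theta.size

    def _require_cov(self) -> np.ndarray:
        if self.cov_params is None:
            raise ValueError("model was fitted with se=False")
        return self.cov_params

    def bse_centered(self) -> np.ndarray:
        """SEs in the centered parameterisation, shape (4, 2 + k)."""
        cov = self._require_cov()
        return np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(
            4, 2 + len(self.model.covariates))

    def cov_params_decentered(self) -> np.ndarray:
        """Covariance transformed to the de-centered coefficients."""
        p = self.k_params
        k = len(self.model.covariates)
        J = np.eye(p)
        for r in range(4):
            row = r * (2 + k)
            J[row, row + 1] = -self.model.age_center
        return J @ self._require_cov() @ J.T

    def relative_risk_ratios(self) -> list[RrrEstimate]:
        """exp(coefficient) per transition and covariate, with Wald 95% CI
        and two-sided p-value."""
        bse = self.bse_centered()
        out = []
        for r, label in enumerate(TRANSITION_LABELS):
            for c, name in enumerate(self.model.covariates):
                coef = float(self.params.cov_coefs[r, c])
                se = float(bse[r, 2 + c])
                z = coef / se if se > 0 else np.inf * np.sign(coef) if coef else 0.0
                p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
                out.append(RrrEstimate(
                    transition=label, covariate=name, coef=coef, se=se,
                    rrr=float(np.exp(coef)),
                    ci=(float(np.exp(coef - Z95 * se)),
                        float(np.exp(coef + Z95 * se))),
                    p_value=float(p if z != 0 else 1.0)))
        return out

    # ------------------------------------------------- expectancy delegation

    def expectancy(self, age: float, profile: Mapping[str, int],
                   weighting: str = "disability-free", method: str = "bootstrap",
                   n_boot: int = 1000, seed: int | None = None,
                   closing_age: float = 115.0):
        """Health expectancies (TLE/DFLE/DLE) with SEs and 95% CIs."""
        from .expectancy import expectancy_uncertainty
        return expectancy_uncertainty(
            self, profile, age, weighting=weighting, method=method,
            n_boot=n_boot, seed=seed, closing_age=closing_age)

    # -------------------------------------------------------------- summary

    def summary(self) -> str:
        bse = self.bse_centered() if self.cov_params is not None else None
        k = len(self.model.covariates)
        lines = []
        lines.append("Multi-state disability model (monthly embedded chain)"
                     if self.model.steps_per_year == 12 else
                     f"Multi-state disability model ({self.model.steps_per_year}"
                     " steps/year)")
        lines.append(f"Individuals: {self.model.nobs}    "
                     f"log-likelihood: {self.llf:.3f}    "
                     f"converged: {self.converged}")
        c = self.model.data.counts
        lines.append(f"Observed pairs 0->1: {c['0->1']}  1->0: {c['1->0']}  "
                     f"deaths: {c['death_from_0'] + c['death_from_1']}")
        if self.separation_flag:
            lines.append("WARNING: coefficient at separation guard")
        lines.append("")
        hdr = f"{'transition':<16}{'term':<12}{'coef':>10}{'se':>9}" \
              f"{'z':>8}{'P>|z|':>8}  [95% CI]"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        terms = ["const", "age"] + list(self.model.covariates)
        mat = np.column_stack([self.params_centered.intercepts,
                               self.params_centered.age_slopes,
                               self.params_centered.cov_coefs.reshape(4, k)])
        for r, label in enumerate(TRANSITION_LABELS):
            for j, term in enumerate(terms):
                coef = mat[r, j]
                if bse is not None and bse[r, j] > 0:
                    se = bse[r, j]
                    z = coef / se
                    p = 2 * stats.norm.sf(abs(z))
                    lines.append(
                        f"{label:<16}{term:<12}{coef:>10.4f}{se:>9.4f}"
                        f"{z:>8.2f}{p:>8.3f}  [{coef - Z95 * se:.4f}, "
                        f"{coef + Z95 * se:.4f}]")
                else:
                    lines.append(f"{label:<16}{term:<12}{coef:>10.4f}"
                                 f"{'':>9}{'':>8}{'':>8}")
        lines.append("")
        lines.append(f"(age centered at {self.model.age_center:g} years; "
                     "'const' is the logit at the centering age)")
        return "\n".join(lines)

    # -------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.model.covariates),
            "age_center": self.model.age_center,
            "steps_per_year": self.model.steps_per_year,
            "theta_centered": self._theta.tolist(),
            "cov_params": None if self.cov_params is None
            else self.cov_params.tolist(),
            "llf": self.llf,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "separation_flag": self.separation_flag,
            "cov_flags": list(self.cov_flags),
            "n_individuals": self.model.nobs,
            "counts": self.model.data.counts,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


class LoadedResults:
    """Deserialized fit: enough surface for expectancies and contrasts."""

    def __init__(self, payload: dict):
        self.params_centered = TransitionParams.from_vector(
            np.asarray(payload["theta_centered"]),
            covariates=tuple(payload["covariates"]),
            steps_per_year=int(payload["steps_per_year"]),
            age_center=float(payload["age_center"]))
        self.params = self.params_centered.with_age_center(0.0)
        cov = payload.get("cov_params")
        self.cov_params = None if cov is None else np.asarray(cov, dtype=float)
        self.llf = payload.get("llf")
        self.converged = payload.get("converged", True)
        self.cov_flags = tuple(payload.get("cov_flags", ()))

    expectancy = DisabilityMarkovResults.expectancy


def load_results(path: str | Path) -> LoadedResults:
    with open(path) as fh:
        return LoadedResults(json.load(fh))
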