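"""Reproducible validation experiments for the whole pipeline.

Each function runs one self-contained study at its stated conditions and
returns plain numbers: agreement of the fitter with a direct multinomial
regression on fully observed monthly data, exactness of latent-state
marginalisation, Wald confidence-interval coverage under the survey design,
agreement of matrix-product expectancies with microsimulation, calibration
of the two-sample Z contrast under the null, and the published-table
contrast arithmetic.  The acceptance test suite and the acceptance script
are thin wrappers over these.
"""

from __future__ import annotations

import numpy as np

from .chain import interval_probability
from .cohort import (default_true_params, generate_cohort, preset,
                     simulate_expectancies)
from .contrasts import expectancy_contrast
from .expectancy import expectancy_uncertainty, state_expectancies
from .model import DisabilityMarkovModel, individual_log_likelihood
from .panel import age_in_months
from .params import TransitionParams
from .published import published_loss_table, published_printed_losses

BEST_PROFILE = dict(education=1, obese=0, smoker=0, exercise=1)

#: survey design of the recovery / calibration experiments: 8 three-yearly
#: waves over 21 years, baseline age 70-75
_WAVES_3Y = tuple(range(0, 253, 36))


def contrast_arithmetic() -> dict:
    """Loss/gain rows of the published tables recomputed from the printed
    group expectancies; returns the computed rows and their maximum
    absolute deviation from the printed loss rows."""
    out = {"rows": {}, "max_abs_dev": 0.0, "n_cells": 0}
    for cohort in ("1921-26", "1946-51"):
        got = published_loss_table(cohort)
        printed = published_printed_losses(cohort)
        out["rows"][cohort] = got
        for (_, g), (_, p) in zip(got.iterrows(), printed.iterrows()):
            for q in ("tle", "dfle", "dle"):
                out["max_abs_dev"] = max(out["max_abs_dev"],
                                         abs(float(g[q]) - float(p[q])))
                out["n_cells"] += 1
    return out


def oracle_equivalence(seed: int, n_individuals: int = 5000,
                       n_months: int = 120) -> dict:
    """Fit on fully observed monthly data against a direct multinomial
    logistic regression on the (state, next state) records.

    With every month observed nothing is latent, so the interval-censored
    likelihood collapses to an ordinary multinomial logit per origin state;
    the two estimates must agree to optimizer precision.
    """
    import statsmodels.api as sm

    tp = default_true_params(covariates=("obese",))
    cfg = preset("cohort1921", n_individuals=n_individuals, seed=seed,
                 wave_offsets_months=tuple(range(n_months + 1)),
                 interview_jitter_days=0, wave_response_prob=1.0,
                 true_params=tp, covariate_prevalences={"obese": 0.25})
    ds = generate_cohort(cfg)
    res = DisabilityMarkovModel(ds, covariates=("obese",),
                                age_center=70.0).fit(se=False)
    rows = []
    for r in ds:
        obs = [(age_in_months(r.birth_year, r.birth_month, w.date), w.state)
               for w in r.waves]
        for (ta, sa), (tb, sb) in zip(obs, obs[1:]):
            rows.append((sa, sb, ta / 12 - 70.0, r.obese))
        d = r.death_age_months()
        if d is not None:
            tl, sl = obs[-1]
            rows.append((sl, 2, d / 12 - 70.0, r.obese))
    arr = np.asarray(rows)
    direct = {}
    for orig in (0, 1):
        sub = arr[arr[:, 0] == orig]
        y = sub[:, 1].astype(int)
        if orig == 1:  # recode so "stay" is the reference category 0
            y = np.array([{1: 0, 0: 1, 2: 2}[v] for v in y])
        X = sm.add_constant(sub[:, 2:4])
        fit = sm.MNLogit(y, X).fit(method="newton", maxiter=300,
                                   disp=0, tol=1e-13)
        direct[orig] = np.asarray(fit.params)
    pc = res.params_centered
    ours = {
        (0, 1): (pc.intercepts[0], pc.age_slopes[0], pc.cov_coefs[0, 0]),
        (0, 2): (pc.intercepts[1], pc.age_slopes[1], pc.cov_coefs[1, 0]),
        (1, 0): (pc.intercepts[2], pc.age_slopes[2], pc.cov_coefs[2, 0]),
        (1, 2): (pc.intercepts[3], pc.age_slopes[3], pc.cov_coefs[3, 0]),
    }
    col = {(0, 1): 0, (0, 2): 1, (1, 0): 0, (1, 2): 1}
    max_diff = max(
        float(np.max(np.abs(np.asarray(v) - direct[i][:, col[i, j]])))
        for (i, j), v in ours.items())
    return {"max_coef_diff": max_diff, "n_individuals": n_individuals,
            "n_records": len(arr)}


def marginalization_error() -> dict:
    """Interval probabilities with latent intermediate states against
    brute-force path enumeration (3 and 9 paths), and a skipped-wave
    likelihood against explicit latent-state summation."""
    from scipy.special import softmax

    p = TransitionParams(intercepts=[-2.0, -3.0, -1.5, -2.5],
                         age_slopes=[0.05, 0.08, -0.02, 0.06],
                         age_center=70.0)

    def step(age):
        eta = p.intercepts + p.age_slopes * (age - p.age_center)
        m = np.eye(3)
        m[0] = softmax([0.0, eta[0], eta[1]])
        m[1] = softmax([eta[2], 0.0, eta[3]])
        return m

    err = 0.0
    mats = [step(70.0 + k / 12) for k in range(3)]
    for i in (0, 1):
        for j in (0, 1, 2):
            brute3 = sum(mats[0][i, s] * mats[1][s, j] for s in range(3))
            err = max(err, abs(
                interval_probability(i, 70.0, j, 70.0 + 2 / 12, {}, p)
                - brute3))
            brute9 = sum(mats[0][i, s1] * mats[1][s1, s2] * mats[2][s2, j]
                         for s1 in range(3) for s2 in range(3))
            err = max(err, abs(
                interval_probability(i, 70.0, j, 70.0 + 3 / 12, {}, p)
                - brute9))
    # skipped-wave record: likelihood marginalises the latent wave state
    import datetime as dt

    from .panel import IndividualRecord, WaveObservation
    rec = IndividualRecord(id="s", birth_month=6, birth_year=1926, waves=[
        WaveObservation(date=dt.date(1996, 6, 15), state=0),
        WaveObservation(date=dt.date(1999, 6, 15), state=-1),
        WaveObservation(date=dt.date(2002, 6, 15), state=1)])
    t0, t1, t2 = (age_in_months(1926, 6, w.date) for w in rec.waves)
    P1 = np.linalg.multi_dot([step(t / 12) for t in range(t0, t1)])
    P2 = np.linalg.multi_dot([step(t / 12) for t in range(t1, t2)])
    brute = np.log(sum(P1[0, s] * P2[s, 1] for s in range(3)))
    err = max(err, abs(individual_log_likelihood(rec, p) - brute))
    return {"max_abs_error": float(err)}


def wald_coverage(seed: int, n_individuals: int = 2000,
                  n_replicates: int = 200) -> dict:
    """Empirical coverage of 95% Wald CIs for every coefficient under the
    3-yearly survey design (jittered interviews, 5% wave non-response)."""
    tp = default_true_params(covariates=("obese",))
    truth = tp.with_age_center(70.0).to_vector()
    hits = np.zeros(truth.size)
    n_conv = 0
    for rep in range(n_replicates):
        cfg = preset("cohort1921", n_individuals=n_individuals,
                     seed=seed + rep, wave_offsets_months=_WAVES_3Y,
                     true_params=tp, covariate_prevalences={"obese": 0.2})
        res = DisabilityMarkovModel(generate_cohort(cfg),
                                    covariates=("obese",),
                                    age_center=70.0).fit()
        if not res.converged:
            continue
        n_conv += 1
        est = res.params_centered.to_vector()
        se = np.sqrt(np.clip(np.diag(res.cov_params), 0.0, None))
        hits += np.abs(est - truth) <= 1.959963984540054 * se
    coverage = hits / max(n_conv, 1)
    return {"coverage": coverage, "min_coverage": float(coverage.min()),
            "max_coverage": float(coverage.max()),
            "mean_coverage": float(coverage.mean()),
            "n_converged": n_conv, "n_replicates": n_replicates}


def expectancy_vs_microsimulation(seed: int, n_paths: int = 100_000) -> dict:
    """Matrix-product TLE/DFLE/DLE against microsimulation means, the
    TLE = DFLE + DLE identity, and the geometric closed-form limit."""
    tp = default_true_params()
    rng = np.random.default_rng(seed)
    mc = simulate_expectancies(tp, BEST_PROFILE, 70.0, n_paths, rng)
    e = state_expectancies(tp, BEST_PROFILE, 70.0)
    zmax = max(abs(e.value(q) - mc[q]) / mc[f"{q}_mc_se"]
               for q in ("TLE", "DFLE", "DLE"))
    identity = abs(e.tle - (e.dfle + e.dle))
    # zero-disability constant-hazard limit
    q = 0.004
    gp = TransitionParams(
        intercepts=[-1e3, float(np.log(q / (1 - q))), -1e3, -1e3],
        age_slopes=np.zeros(4))
    eg = state_expectancies(gp, {}, 70.0, closing_age=470.0)
    s = 1 - q
    geom_err = abs(eg.tle - (s / (12 * (1 - s)) + 0.5 / 12))
    return {"max_z": float(zmax), "tle_identity_error": float(identity),
            "geometric_error": float(geom_err), "n_paths": n_paths,
            "tle": e.tle, "dfle": e.dfle, "dle": e.dle,
            "mc": {k: mc[k] for k in mc}}


def null_calibration(seed: int, n_per_arm: int = 1000,
                     n_replicates: int = 200) -> dict:
    """Two-sample Z contrast between two groups simulated from identical
    parameters: the rejection rate at alpha = 0.05 across replicate fits
    estimates the size of the test."""
    tp = default_true_params(covariates=())
    rejections = {"TLE": 0, "DFLE": 0, "DLE": 0}
    n_done = 0
    for rep in range(n_replicates):
        ests = []
        for arm in range(2):
            cfg = preset("cohort1921", n_individuals=n_per_arm,
                         seed=seed + 2 * rep + arm + 1_000_000,
                         wave_offsets_months=_WAVES_3Y, true_params=tp,
                         covariate_prevalences={})
            res = DisabilityMarkovModel(generate_cohort(cfg), covariates=(),
                                        age_center=70.0).fit()
            ests.append(expectancy_uncertainty(res, {}, 70.0, method="delta"))
        con = expectancy_contrast(ests[0], ests[1])
        n_done += 1
        for quantity in rejections:
            rejections[quantity] += con[quantity].p_value < 0.05
    return {"rejection_rate": {k: v / n_done for k, v in rejections.items()},
            "n_replicates": n_done}
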