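"""Elementary step matrices and interval probabilities of the embedded chain.

Observed transitions over a multi-month interval are products of one-step
(by default one-month) 3x3 stochastic matrices, each evaluated at the exact
age attained at the start of its step.  This module is the plain-NumPy
reference path; the fitter uses a compiled equivalent.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .params import TransitionParams

__all__ = ["step_transition_matrix", "step_matrices", "interval_probability"]


def _rows_from_logits(eta: np.ndarray) -> np.ndarray:
    """Transient-origin probability rows from destination logits.

    Parameters
    ----------
    eta : ndarray, shape (..., 4)
        Logits in transition order (0->1, 0->2, 1->0, 1->2), with staying as
        the zero-logit reference.

    Returns
    -------
    ndarray, shape (..., 2, 3)
        Rows for origins 0 and 1 over destinations (0, 1, 2).  Computed via
        a max-shifted softmax, so the result is finite (and row-stochastic)
        for any finite logits.
    """
    eta = np.asarray(eta, dtype=float)
    z = np.zeros(eta.shape[:-1])
    # origin 0: destinations (stay=0, 1, 2); origin 1: (0, stay=1, 2)
    l0 = np.stack([z, eta[..., 0], eta[..., 1]], axis=-1)
    l1 = np.stack([eta[..., 2], z, eta[..., 3]], axis=-1)
    logit = np.stack([l0, l1], axis=-2)
    logit = logit - logit.max(axis=-1, keepdims=True)
    p = np.exp(logit)
    return p / p.sum(axis=-1, keepdims=True)


def step_matrices(ages: np.ndarray, x: np.ndarray,
                  params: TransitionParams) -> np.ndarray:
    """Full 3x3 one-step matrices at each age in ``ages`` (years).

    The death row is exactly (0, 0, 1): death is absorbing by construction.
    """
    rows = _rows_from_logits(params.logits(np.asarray(ages, float), x))
    out = np.zeros(rows.shape[:-2] + (3, 3))
    out[..., :2, :] = rows
    out[..., 2, 2] = 1.0
    return out


def step_transition_matrix(age: float, profile: Mapping[str, int] | None,
                           params: TransitionParams) -> np.ndarray:
    """One-step 3x3 transition probability matrix at exact ``age`` (years).

    Row i gives P(state at next step = j | state now = i) for the given
    covariate profile.  Rows sum to one; the death row is the identity row.
    """
    if not np.isfinite(age):
        raise ValueError("age must be finite")
    x = params.profile_vector(profile)
    return step_matrices(np.asarray(age, float), x, params)


def interval_probability(state_i: int, age_start: float, state_j: int,
                         age_end: float, profile: Mapping[str, int] | None,
                         params: TransitionParams) -> float:
    """Probability of being in ``state_j`` at ``age_end`` given ``state_i``
    at ``age_start``.

    The interval is rounded to a whole number of elementary steps and the
    result is entry (i, j) of the ordered product of one-step matrices, each
    evaluated at the age attained at the start of its step.  Latent states
    in between (including earlier death when j = 2) are marginalised by the
    matrix product itself.  A zero-length interval returns the indicator of
    i == j.
    """
    if age_end < age_start:
        raise ValueError("age_end must be >= age_start")
    for s in (state_i, state_j):
        if s not in (0, 1, 2):
            raise ValueError(f"invalid state {s!r}")
    spy = params.steps_per_year
    n_steps = int(round((age_end - age_start) * spy))
    if n_steps == 0:
        return float(state_i == state_j)
    x = params.profile_vector(profile)
    ages = age_start + np.arange(n_steps) / spy
    mats = step_matrices(ages, x, params)
    out = mats[0]
    for t in range(1, n_steps):
        out = out @ mats[t]
    return float(out[state_i, state_j])
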