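"""Compiled interval-censored likelihood and analytic gradient.

The data enter as "episodes": an episode runs from a known-state wave to
the next known-state wave (skipped or unknown waves simply lengthen it) or
to an exactly dated death.  The episode probability is the corresponding
entry of the product of one-step transient submatrices, with deaths
contributing survival to the death month times the one-step death
probability of that month, marginalised over the latent transient state.

The gradient is assembled by an adjoint (forward/backward) sweep per
episode: contributions to each transition's destination logit at each step
are accumulated on a (transition, step, covariate-group) grid and then
contracted with the design (intercept, centered age, covariate values).
Episodes identical in (group, months, states) are collapsed with weights.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: transition order (matches params.TRANSITIONS)
_ORIG = (0, 0, 1, 1)
_DEST = (1, 2, 0, 2)

_PROB_FLOOR = 1e-300  # guards log underflow during wild line-search steps


@njit(cache=True)
def _step_probs(B, ages_c, Xg):
    """One-step probability rows P[t, g, origin, dest] for transient origins."""
    T = ages_c.shape[0]
    G = Xg.shape[0]
    k = Xg.shape[1]
    P = np.empty((T, G, 2, 3))
    for g in range(G):
        base = np.empty(4)
        for r in range(4):
            b = B[r, 0]
            for c in range(k):
                b += B[r, 2 + c] * Xg[g, c]
            base[r] = b
        for t in range(T):
            a = ages_c[t]
            e01 = base[0] + B[0, 1] * a
            e02 = base[1] + B[1, 1] * a
            e10 = base[2] + B[2, 1] * a
            e12 = base[3] + B[3, 1] * a
            m = max(0.0, max(e01, e02))
            z0 = np.exp(0.0 - m)
            z1 = np.exp(e01 - m)
            z2 = np.exp(e02 - m)
            s = z0 + z1 + z2
            P[t, g, 0, 0] = z0 / s
            P[t, g, 0, 1] = z1 / s
            P[t, g, 0, 2] = z2 / s
            m = max(0.0, max(e10, e12))
            z0 = np.exp(e10 - m)
            z1 = np.exp(0.0 - m)
            z2 = np.exp(e12 - m)
            s = z0 + z1 + z2
            P[t, g, 1, 0] = z0 / s
            P[t, g, 1, 1] = z1 / s
            P[t, g, 1, 2] = z2 / s
    return P


@njit(cache=True)
def _loglik_core(B, ages_c, Xg, t0, tend, i0, jend, gidx, w, need_grad):
    """Weighted log-likelihood (and gradient w.r.t. B) over all episodes.

    B has shape (4, 2 + k): per transition (intercept, age slope, covariate
    coefficients), in the centered-age parameterisation of ``ages_c``.
    """
    P = _step_probs(B, ages_c, Xg)
    T = ages_c.shape[0]
    G = Xg.shape[0]
    k = Xg.shape[1]
    n_ep = t0.shape[0]
    if need_grad:
        S = np.zeros((4, T, G))
    else:
        S = np.zeros((4, 1, 1))
    maxlen = 0
    for e in range(n_ep):
        if tend[e] - t0[e] > maxlen:
            maxlen = tend[e] - t0[e]
    A = np.empty((maxlen + 1, 2))
    iR = _ORIG
    jR = _DEST
    ll = 0.0
    for e in range(n_ep):
        g = gidx[e]
        a0 = t0[e]
        a1 = tend[e]
        L = a1 - a0
        A[0, 0] = 1.0 if i0[e] == 0 else 0.0
        A[0, 1] = 1.0 - A[0, 0]
        for s in range(L):
            t = a0 + s
            x0 = A[s, 0]
            x1 = A[s, 1]
            A[s + 1, 0] = x0 * P[t, g, 0, 0] + x1 * P[t, g, 1, 0]
            A[s + 1, 1] = x0 * P[t, g, 0, 1] + x1 * P[t, g, 1, 1]
        if jend[e] == 2:
            prob = A[L, 0] * P[a1, g, 0, 2] + A[L, 1] * P[a1, g, 1, 2]
        else:
            prob = A[L, jend[e]]
        if prob < _PROB_FLOOR:
            prob = _PROB_FLOOR
        ll += w[e] * np.log(prob)
        if not need_grad:
            continue
        we = w[e]
        if jend[e] == 2:
            b0 = P[a1, g, 0, 2]
            b1 = P[a1, g, 1, 2]
            # direct dependence of the death column on the logits at a1
            for r in range(4):
                ir = iR[r]
                jr = jR[r]
                d = 1.0 if jr == 2 else 0.0
                S[r, a1, g] += we * A[L, ir] * P[a1, g, ir, 2] \
                    * (d - P[a1, g, ir, jr]) / prob
        elif jend[e] == 0:
            b0, b1 = 1.0, 0.0
        else:
            b0, b1 = 0.0, 1.0
        for s in range(L - 1, -1, -1):
            t = a0 + s
            qb0 = P[t, g, 0, 0] * b0 + P[t, g, 0, 1] * b1
            qb1 = P[t, g, 1, 0] * b0 + P[t, g, 1, 1] * b1
            for r in range(4):
                ir = iR[r]
                jr = jR[r]
                if jr == 0:
                    bj = b0
                elif jr == 1:
                    bj = b1
                else:
                    bj = 0.0
                qbi = qb0 if ir == 0 else qb1
                S[r, t, g] += we * A[s, ir] * P[t, g, ir, jr] \
                    * (bj - qbi) / prob
            b0 = qb0
            b1 = qb1
    grad = np.zeros((4, 2 + k))
    if need_grad:
        for r in range(4):
            for t in range(T):
                rowsum = 0.0
                for g in range(G):
                    v = S[r, t, g]
                    rowsum += v
                    for c in range(k):
                        grad[r, 2 + c] += v * Xg[g, c]
                grad[r, 0] += rowsum
                grad[r, 1] += rowsum * ages_c[t]
    return ll, grad


class EpisodeData:
    """Collapsed episode arrays ready for the compiled kernel."""

    def __init__(self, t0, tend, i0, jend, gidx, w, Xg, t_min, t_max,
                 counts, n_individuals, n_dropped):
        self.t0 = t0
        self.tend = tend
        self.i0 = i0
        self.jend = jend
        self.gidx = gidx
        self.w = w
        self.Xg = Xg
        self.t_min = t_min          # global step index of local step 0
        self.t_max = t_max
        self.counts = counts        # observed pair/death tallies
        self.n_individuals = n_individuals
        self.n_dropped = n_dropped  # individuals with death but no known state
        self.total_weight = float(w.sum()) if len(w) else 0.0

    @property
    def n_steps(self) -> int:
        return self.t_max - self.t_min + 1

    def ages_centered(self, steps_per_year: int, age_center: float) -> np.ndarray:
        return (self.t_min + np.arange(self.n_steps)) / steps_per_year - age_center

    def loglike(self, B: np.ndarray, ages_c: np.ndarray,
                need_grad: bool) -> tuple[float, np.ndarray]:
        return _loglik_core(B, ages_c, self.Xg, self.t0, self.tend, self.i0,
                            self.jend, self.gidx, self.w, need_grad)


def build_episodes(dataset, covariates, steps_per_year=12) -> EpisodeData:
    """Extract, index and collapse likelihood episodes from a panel."""
    from .panel import age_in_months

    rows = []          # (t0, tend, i0, jend, x...)
    xs = []
    counts = {"0->1": 0, "1->0": 0, "0->0": 0, "1->1": 0,
              "death_from_0": 0, "death_from_1": 0}
    n_dropped = 0
    n_used = 0
    for rec in dataset:
        x = []
        for c in covariates:
            v = rec.covariate(c)
            if v is None:
                raise ValueError(
                    f"{rec.id}: missing covariate {c!r}; apply exclusions first")
            x.append(float(v))
        obs = []
        for wv in rec.waves:
            if wv.state in (0, 1):
                t = age_in_months(rec.birth_year, rec.birth_month, wv.date)
                t = int(round(t * steps_per_year / 12))
                if not obs or t > obs[-1][0]:
                    obs.append((t, wv.state))
        d = rec.death_age_months()
        if d is not None:
            d = int(round(d * steps_per_year / 12))
        if not obs:
            if d is not None:
                n_dropped += 1  # a death with no prior state carries no likelihood
            continue
        n_used += 1
        for (ta, sa), (tb, sb) in zip(obs, obs[1:]):
            rows.append((ta, tb, sa, sb))
            xs.append(x)
            counts[f"{sa}->{sb}"] += 1
        if d is not None:
            tl, sl = obs[-1]
            rows.append((tl, max(d, tl), sl, 2))
            xs.append(x)
            counts[f"death_from_{sl}"] += 1
    if not rows:
        raise ValueError("dataset contains no usable transitions")
    ep = np.asarray(rows, dtype=np.int64)
    X = np.asarray(xs, dtype=float)
    Xg, gidx = np.unique(X, axis=0, return_inverse=True)
    t_min = int(ep[:, 0].min())
    t_max = int(ep[:, 1].max())
    ep[:, :2] -= t_min
    stacked = np.column_stack([gidx, ep])
    uniq, w = np.unique(stacked, axis=0, return_counts=True)
    return EpisodeData(
        t0=np.ascontiguousarray(uniq[:, 1]),
        tend=np.ascontiguousarray(uniq[:, 2]),
        i0=np.ascontiguousarray(uniq[:, 3]),
        jend=np.ascontiguousarray(uniq[:, 4]),
        gidx=np.ascontiguousarray(uniq[:, 0]),
        w=w.astype(float),
        Xg=np.ascontiguousarray(Xg),
        t_min=t_min, t_max=t_max, counts=counts,
        n_individuals=n_used, n_dropped=n_dropped,
    )
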