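"""Profile contrasts: loss/gain in expectancy between covariate profiles.

The headline comparisons are two-sample Z-tests on the difference of two
expectancy estimates, combining their standard errors under independence
(the profiles come from separate groups).  A correlated-delta alternative,
which accounts for the two profiles sharing one fitted coefficient vector,
is available behind an explicit function and labelled in its output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expectancy import (QUANTITIES, ExpectancyEstimate, _delta_gradients,
                         expectancy_uncertainty)
from .model import Z95

__all__ = ["ContrastResult", "contrast_values", "expectancy_contrast",
           "expectancy_contrast_correlated", "build_expectancy_table"]


@dataclass(frozen=True)
class ContrastResult:
    """Difference (B - A) of one expectancy quantity between two profiles."""

    quantity: str
    label_a: str
    label_b: str
    value_a: float
    value_b: float
    difference: float
    se: float
    ci: tuple[float, float]
    z: float
    p_value: float
    se_method: str = "independent"


def contrast_values(value_a: float, se_a: float, value_b: float, se_b: float,
                    quantity: str = "TLE", label_a: str = "A",
                    label_b: str = "B") -> ContrastResult:
    """Two-sample Z-test on a difference of estimates.

    diff = B - A, SE = sqrt(SE_A^2 + SE_B^2), 95% CI = diff +/- 1.96 SE,
    p = 2 Phi(-|Z|).  Requires nonnegative SEs, not both zero.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    se = float(np.hypot(se_a, se_b))
    if se == 0.0:
        raise ValueError("both standard errors are zero: no test possible")
    diff = float(value_b - value_a)
    z = diff / se
    return ContrastResult(
        quantity=quantity, label_a=label_a, label_b=label_b,
        value_a=float(value_a), value_b=float(value_b), difference=diff,
        se=se, ci=(diff - Z95 * se, diff + Z95 * se), z=float(z),
        p_value=float(2.0 * stats.norm.sf(abs(z))))


def expectancy_contrast(e_a: ExpectancyEstimate, e_b: ExpectancyEstimate,
                        label_a: str = "A", label_b: str = "B",
                        ) -> dict[str, ContrastResult]:
    """Contrast two expectancy estimates on all three quantities."""
    for e in (e_a, e_b):
        if e.se is None:
            raise ValueError("estimates must carry standard errors")
    return {q: contrast_values(e_a.value(q), e_a.se[q], e_b.value(q),
                               e_b.se[q], quantity=q, label_a=label_a,
                               label_b=label_b) for q in QUANTITIES}


def expectancy_contrast_correlated(results, profile_a: Mapping[str, int],
                                   profile_b: Mapping[str, int], age: float,
                                   weighting: str = "disability-free",
                                   closing_age: float = 115.0,
                                   label_a: str = "A", label_b: str = "B",
                                   ) -> dict[str, ContrastResult]:
    """Delta-method contrast honouring the covariance between two profiles
    evaluated on the same fitted model (SE of B - A uses (g_B - g_A))."""
    cov = results.cov_params
    if cov is None:
        raise ValueError("fit carries no parameter covariance")
    from .expectancy import state_expectancies
    ga = _delta_gradients(results, profile_a, age, weighting, closing_age)
    gb = _delta_gradients(results, profile_b, age, weighting, closing_age)
    ea = state_expectancies(results.params_centered, profile_a, age,
                            weighting, closing_age)
    eb = state_expectancies(results.params_centered, profile_b, age,
                            weighting, closing_age)
    out = {}
    for q in QUANTITIES:
        g = gb[q] - ga[q]
        se = float(np.sqrt(max(g @ cov @ g, 0.0)))
        diff = eb.value(q) - ea.value(q)
        if se == 0.0:
            raise ValueError("degenerate contrast: zero standard error")
        z = diff / se
        out[q] = ContrastResult(
            quantity=q, label_a=label_a, label_b=label_b,
            value_a=ea.value(q), value_b=eb.value(q), difference=float(diff),
            se=se, ci=(diff - Z95 * se, diff + Z95 * se), z=float(z),
            p_value=float(2.0 * stats.norm.sf(abs(z))),
            se_method="correlated-delta")
    return out


def _estimate_row(stratum: str, label: str, e: ExpectancyEstimate,
                  n: int | None = None) -> dict:
    row = dict(stratum=stratum, kind="estimate", label=label, vs="", n=n)
    for q in QUANTITIES:
        lq = q.lower()
        row[lq] = e.value(q)
        row[f"{lq}_lo"], row[f"{lq}_hi"] = e.ci[q]
        row[f"{lq}_se"] = e.se[q]
        row[f"{lq}_p"] = np.nan
    return row


def _loss_row(stratum: str, kind: str, label: str, ref_label: str,
              contrasts: dict[str, ContrastResult]) -> dict:
    row = dict(stratum=stratum, kind=kind, label=label, vs=ref_label, n=None)
    for q in QUANTITIES:
        c = contrasts[q]
        lq = q.lower()
        row[lq] = c.difference
        row[f"{lq}_lo"], row[f"{lq}_hi"] = c.ci
        row[f"{lq}_se"] = c.se
        row[f"{lq}_p"] = c.p_value
    return row


def build_expectancy_table(results_by_stratum: Mapping[str, object],
                           profiles: Mapping[str, Mapping[str, Mapping[str, int]]],
                           age: float, reference: str,
                           cross: tuple[tuple[str, str], tuple[str, str]] | None = None,
                           weighting: str = "disability-free",
                           method: str = "bootstrap", n_boot: int = 1000,
                           seed: int | None = None, closing_age: float = 115.0,
                           group_sizes: Mapping[tuple[str, str], int] | None = None,
                           debug: bool = False) -> pd.DataFrame:
    """Expectancy table with loss/gain rows, one block per stratum.

    ``profiles`` maps stratum -> {label -> covariate profile}; every
    stratum must contain the ``reference`` label, whose row all loss rows
    in the block subtract from.  ``cross`` is an optional pair
    ((stratum_b, label_b), (stratum_a, label_a)) adding a cross-stratum
    loss row B - A (the least-favourable versus most-favourable headline
    contrast); when omitted and exactly two strata are present, the
    lowest-DFLE profile of the last stratum is contrasted against the
    first stratum's reference.
    """
    estimates: dict[tuple[str, str], ExpectancyEstimate] = {}
    rows = []
    for s, (stratum, labels) in enumerate(profiles.items()):
        if reference not in labels:
            raise ValueError(f"stratum {stratum!r} lacks reference "
                             f"profile {reference!r}")
        try:
            results = results_by_stratum[stratum]
        except KeyError:
            raise ValueError(f"no fitted model for stratum {stratum!r}")
        for k, (label, profile) in enumerate(labels.items()):
            estimates[stratum, label] = expectancy_uncertainty(
                results, profile, age, weighting=weighting, method=method,
                n_boot=n_boot, closing_age=closing_age,
                seed=None if seed is None else seed + 1000 * s + k)
        for label in labels:
            n = group_sizes.get((stratum, label)) if group_sizes else None
            rows.append(_estimate_row(stratum, label, estimates[stratum, label], n))
        for label in labels:
            if label == reference and not debug:
                continue
            con = expectancy_contrast(estimates[stratum, reference],
                                      estimates[stratum, label],
                                      label_a=reference, label_b=label)
            rows.append(_loss_row(stratum, "loss", label, reference, con))
    if cross is None and len(profiles) == 2:
        strata = list(profiles)
        ref_stratum, worst_stratum = strata[0], strata[-1]
        worst_label = min(profiles[worst_stratum],
                          key=lambda lb: estimates[worst_stratum, lb].dfle)
        cross = ((worst_stratum, worst_label), (ref_stratum, reference))
    if cross is not None:
        (sb, lb), (sa, la) = cross
        con = expectancy_contrast(estimates[sa, la], estimates[sb, lb],
                                  label_a=f"{sa}:{la}", label_b=f"{sb}:{lb}")
        rows.append(_loss_row(f"{sb} vs {sa}", "cross", lb, la, con))
    return pd.DataFrame(rows)
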