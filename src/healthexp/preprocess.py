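"""Survey-to-analysis preprocessing.

Covers the SF-36 physical-functioning (PF) scale score, the two-part
disability definition (PF score below 40 *and* needing regular help with
daily tasks), covariate backfilling from later waves, and the baseline
exclusion rules (pre-existing disability, underweight, missing covariates).
"""

from __future__ import annotations

from typing import Sequence

from .panel import (COVARIATE_FIELDS, STATE_DISABLED, STATE_FREE, UNKNOWN,
                    PanelDataset)

#: SF-36 PF item response codes
LIMITED_A_LOT = 1
LIMITED_A_LITTLE = 2
NOT_LIMITED = 3

_RESPONSE_ALIASES = {
    "limited_a_lot": LIMITED_A_LOT,
    "limited_a_little": LIMITED_A_LITTLE,
    "not_limited": NOT_LIMITED,
}

#: PF threshold of the disability definition (strict "below")
PF_CUTOFF = 40.0
#: BMI below which individuals are excluded at baseline (strict "below")
UNDERWEIGHT_BMI = 18.5

EXCLUSION_REASONS = ("disability", "underweight", "missing_covariates")


def score_sf36_pf(responses: Sequence) -> float | None:
    """Score the 10-item SF-36 physical functioning scale to 0-100.

    Items are coded 1 (limited a lot), 2 (limited a little), 3 (not
    limited); ``None`` marks a missing item, and the string aliases
    ``"limited_a_lot"`` etc. are accepted.  The raw sum (10-30) maps
    linearly onto 0-100 as (raw - 10) / 20 * 100.  If more than half the
    items are missing the score is missing; otherwise missing items are
    imputed with the person's mean over answered items (half-scale rule).
    """
    items = list(responses)
    if len(items) != 10:
        raise ValueError(f"expected 10 item responses, got {len(items)}")
    values: list[float | None] = []
    for r in items:
        if r is None:
            values.append(None)
        elif isinstance(r, str):
            try:
                values.append(float(_RESPONSE_ALIASES[r]))
            except KeyError:
                raise ValueError(f"unknown item response {r!r}") from None
        elif r in (LIMITED_A_LOT, LIMITED_A_LITTLE, NOT_LIMITED):
            values.append(float(r))
        else:
            raise ValueError(f"unknown item response {r!r}")
    answered = [v for v in values if v is not None]
    if len(answered) < 5:  # more than half missing
        return None
    mean = sum(answered) / len(answered)
    raw = sum(v if v is not None else mean for v in values)
    return (raw - 10.0) / 20.0 * 100.0


def classify_disability(pf_score: float | None,
                        needs_help: bool | None) -> int | None:
    """Derive the 2-level disability state from PF score and help flag.

    Disabled (1) requires *both* a PF score strictly below 40 and needing
    regular help with daily tasks; a score of 40 or more, or not needing
    help, is disability-free (0).  Returns ``None`` when neither rule can
    fire (e.g. score missing while help is needed).
    """
    if pf_score is not None and not 0.0 <= pf_score <= 100.0:
        raise ValueError(f"pf_score outside [0, 100]: {pf_score!r}")
    if pf_score is not None and pf_score >= PF_CUTOFF:
        return STATE_FREE
    if needs_help is False:
        return STATE_FREE
    if pf_score is not None and needs_help is True:
        return STATE_DISABLED
    return None


def derive_states(dataset: PanelDataset) -> PanelDataset:
    """Fill unknown wave states from PF score / needs-help where possible.

    Returns a new dataset; waves whose state is already set are untouched.
    """
    out = dataset.copy()
    for rec in out:
        for w in rec.waves:
            if w.state == UNKNOWN:
                derived = classify_disability(w.pf_score, w.needs_help)
                if derived is not None:
                    w.state = derived
    return out


def backfill_covariates(dataset: PanelDataset) -> PanelDataset:
    """Fill covariates missing at baseline from later waves.

    A record-level (baseline) covariate that is missing takes its earliest
    non-missing wave-level report; observed baseline values are never
    overwritten.  BMI is backfilled by the same rule.
    """
    out = dataset.copy()
    for rec in out:
        for name in COVARIATE_FIELDS + ("bmi",):
            if getattr(rec, name) is None:
                for w in rec.waves:
                    v = getattr(w, name)
                    if v is not None:
                        setattr(rec, name, v)
                        break
    return out


def apply_exclusions(
    dataset: PanelDataset,
    covariates: Sequence[str] = COVARIATE_FIELDS,
) -> tuple[PanelDataset, dict]:
    """Drop baseline-disabled, underweight and covariate-missing individuals.

    Assumes :func:`backfill_covariates` has already run.  Each excluded
    individual is counted once under the first matching reason, in the
    fixed order disability -> underweight -> missing covariates, so the
    per-reason counts partition the excluded set.  Returns the reduced
    dataset and a tally with per-reason counts and the final sample size.
    """
    kept = []
    tally = {r: 0 for r in EXCLUSION_REASONS}
    out = dataset.copy()
    for rec in out:
        reason = None
        baseline_state = rec.waves[0].state if rec.waves else UNKNOWN
        if baseline_state == STATE_DISABLED:
            reason = "disability"
        elif rec.bmi is not None and rec.bmi < UNDERWEIGHT_BMI:
            reason = "underweight"
        elif any(rec.covariate(c) is None for c in covariates):
            reason = "missing_covariates"
        if reason is None:
            kept.append(rec)
        else:
            tally[reason] += 1
            out.exclusion_log.append(f"{rec.id}: excluded ({reason})")
    tally["initial"] = len(out.individuals)
    tally["excluded"] = sum(tally[r] for r in EXCLUSION_REASONS)
    tally["final"] = tally["initial"] - tally["excluded"]
    out.individuals = kept
    return out, tally
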