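"""End-to-end pipeline: simulate/read -> preprocess -> fit -> tables.

`run_pipeline` executes the whole analysis for one or two cohorts from a
single plain-text (YAML) configuration and writes deterministic CSV/JSON
artifacts: per-stratum fit files, the expectancy table with loss/gain
rows, the relative-risk-ratio table, and a run log with seeds and
convergence diagnostics.  Figure rendering (an RRR forest plot) is
optional and headless-safe; the tables are the canonical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import generate_cohort, preset
from .contrasts import build_expectancy_table
from .io import read_panel_csv
from .model import DisabilityMarkovModel
from .panel import PanelDataset
from .preprocess import apply_exclusions, backfill_covariates, derive_states
from .published import PROFILE_DEFINITIONS, REFERENCE_LABEL

__all__ = ["PipelineConfig", "PipelineError", "ConfigError", "run_pipeline"]

_LIFESTYLE = ("obese", "smoker", "exercise")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _default_profiles() -> dict[str, dict[str, dict[str, int]]]:
    labels = list(PROFILE_DEFINITIONS)
    return {"high": {lb: dict(PROFILE_DEFINITIONS[lb]) for lb in labels[:5]},
            "low": {lb: dict(PROFILE_DEFINITIONS[lb]) for lb in labels}}


@dataclass
class PipelineConfig:
    """Study configuration for :func:`run_pipeline`.

    ``cohorts`` maps a cohort name to either a generator preset name
    (``"cohort1921"`` / ``"cohort1946"``) or a panel-CSV path.  Profiles
    are lifestyle combinations per education stratum (at most 6 per
    stratum, the batching convention of the published tables).
    """

    cohorts: Mapping[str, str] = field(
        default_factory=lambda: {"1921-26": "cohort1921",
                                 "1946-51": "cohort1946"})
    n_individuals: int = 2000
    seed: int = 0
    stratify_by: str = "education"
    covariates: tuple[str, ...] = _LIFESTYLE
    profiles: dict = field(default_factory=_default_profiles)
    target_age: float = 70.0
    weighting: str = "disability-free"
    uncertainty_method: str = "bootstrap"
    n_boot: int = 1000
    closing_age: float = 115.0
    steps_per_year: int = 12
    output_dir: str = "healthexp-output"
    make_figure: bool = False

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ConfigError("at least one cohort is required")
        if not self.profiles:
            raise ConfigError("profiles must be nonempty")
        for stratum, labels in self.profiles.items():
            if not labels:
                raise ConfigError(f"stratum {stratum!r} has no profiles")
            if len(labels) > 6:
                raise ConfigError(f"stratum {stratum!r}: at most 6 profiles "
                                  "per stratum")
            if REFERENCE_LABEL not in labels:
                raise ConfigError(f"stratum {stratum!r} lacks the reference "
                                  f"profile {REFERENCE_LABEL!r}")
        if self.uncertainty_method not in ("bootstrap", "delta"):
            raise ConfigError("uncertainty_method must be bootstrap or delta")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)


def _load_cohort(name: str, source: str, cfg: PipelineConfig,
                 seed: int) -> PanelDataset:
    if source in ("cohort1921", "cohort1946"):
        return generate_cohort(preset(source, n_individuals=cfg.n_individuals,
                                      seed=seed))
    return read_panel_csv(source)


def _forest_plot(rrr_frame: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.4 * len(rrr_frame) + 1.5))
    y = np.arange(len(rrr_frame))[::-1]
    ax.errorbar(rrr_frame["rrr"], y,
                xerr=[rrr_frame["rrr"] - rrr_frame["ci_lo"],
                      rrr_frame["ci_hi"] - rrr_frame["rrr"]],
                fmt="o", color="k", ecolor="gray", capsize=2)
    ax.axvline(1.0, color="r", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(rrr_frame["cohort"] + " " + rrr_frame["transition"]
                       + " / " + rrr_frame["covariate"])
    ax.set_xscale("log")
    ax.set_xlabel("relative risk ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the artifact bundle as a dict
    (paths plus in-memory tables) and writes everything under
    ``config.output_dir``.  Any stage failure raises :class:`PipelineError`
    naming the stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_seed": config.seed, "version": __version__,
                 "stages": [], "convergence": {}}
    bundle: dict = {"output_dir": str(out), "tables": {}, "fits": {}}
    rrr_rows = []
    for ci, (cohort, source) in enumerate(config.cohorts.items()):
        tag = cohort.replace("/", "-")
        seed = config.seed + 101 * ci
        try:
            data = _load_cohort(cohort, source, config, seed)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError(f"data:{cohort}", str(exc)) from exc
        try:
            data = derive_states(data)
            data = backfill_covariates(data)
            data, tally = apply_exclusions(
                data, covariates=(config.stratify_by, *config.covariates))
        except Exception as exc:
            raise PipelineError(f"preprocess:{cohort}", str(exc)) from exc
        log["stages"].append({"cohort": cohort, "exclusions": tally})
        try:
            results_by_stratum = {}
            for stratum, value in (("low", 0), ("high", 1)):
                subset = PanelDataset([r for r in data
                                       if r.covariate(config.stratify_by) == value])
                model = DisabilityMarkovModel(
                    subset, covariates=config.covariates,
                    age_center=config.target_age,
                    steps_per_year=config.steps_per_year)
                res = model.fit()
                if not res.converged:
                    raise PipelineError(
                        f"fit:{cohort}:{stratum}",
                        f"no convergence: {res.message}")
                results_by_stratum[stratum] = res
                log["convergence"][f"{cohort}:{stratum}"] = {
                    "converged": res.converged, "llf": res.llf,
                    "grad_norm": res.grad_norm, "n_iter": res.n_iter}
                res.save(out / f"fit_{tag}_{stratum}.json")
            pooled = DisabilityMarkovModel(
                data, covariates=(config.stratify_by, *config.covariates),
                age_center=config.target_age,
                steps_per_year=config.steps_per_year).fit()
            log["convergence"][f"{cohort}:pooled"] = {
                "converged": pooled.converged, "llf": pooled.llf,
                "grad_norm": pooled.grad_norm, "n_iter": pooled.n_iter}
            pooled.save(out / f"fit_{tag}_pooled.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"fit:{cohort}", str(exc)) from exc
        try:
            profiles = {s: {lb: dict(p) for lb, p in labels.items()}
                        for s, labels in config.profiles.items()}
            table = build_expectancy_table(
                results_by_stratum, profiles, config.target_age,
                REFERENCE_LABEL, weighting=config.weighting,
                method=config.uncertainty_method, n_boot=config.n_boot,
                seed=seed + 7, closing_age=config.closing_age)
        except Exception as exc:
            raise PipelineError(f"expectancy:{cohort}", str(exc)) from exc
        table.insert(0, "cohort", cohort)
        table.to_csv(out / f"expectancy_table_{tag}.csv", index=False)
        _write_json(out / f"expectancy_table_{tag}.json",
                    table.to_dict(orient="records"))
        bundle["tables"][cohort] = table
        bundle["fits"][cohort] = results_by_stratum
        for est in pooled.relative_risk_ratios():
            rrr_rows.append(dict(cohort=cohort, transition=est.transition,
                                 covariate=est.covariate, rrr=est.rrr,
                                 ci_lo=est.ci[0], ci_hi=est.ci[1],
                                 p_value=est.p_value))
    rrr = pd.DataFrame(rrr_rows)
    rrr.to_csv(out / "rrr.csv", index=False)
    bundle["tables"]["rrr"] = rrr
    if config.make_figure:
        try:
            _forest_plot(rrr, out / "rrr_forest.png")
        except Exception as exc:
            raise PipelineError("figure", str(exc)) from exc
    _write_json(out / "run_log.json", log)
    bundle["log"] = log
    return bundle
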