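"""End-to-end driver: simulate -> fit -> compare -> associate.

A single :class:`RunConfig` captures every knob and every stage seed, so a
run is reproducible bit-for-bit from its config file; the emitted manifest
records the config hash and per-file checksums to make that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .schedules import ScheduleConfig
from .learners import BAYES_TAG, RW_TAG, LearnerGrid
from .inference import (FitGrid, compare_models, fit_subject,
                        predictive_accuracy)
from .choice_model import policy_trace
from .simulate import TRAIT_NAMES, generate_cohort
from .traits import associate
from .io import export_cohort, write_json
from .simulate import agent_beliefs, AgentSpec
from .choice_model import ParameterVector


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the missing input."""


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    n_subjects: int = 36
    n_trials: int = 290
    learner_grid: LearnerGrid = field(default_factory=LearnerGrid)
    fit_grid: FitGrid = field(default_factory=FitGrid)
    rw_grid_points: int = 20
    rw_alpha_points: int = 10
    n_bootstrap_select: int = 100
    n_bootstrap_corr: int = 10_000
    run_compare: bool = True
    seeds: dict = field(default_factory=lambda: {
        "cohort": 11, "select": 12, "correlate": 13,
    })

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "learner_grid" in d and isinstance(d["learner_grid"], dict):
            lg = dict(d["learner_grid"])
            for key in ("r_bounds", "v_bounds", "k_bounds"):
                if key in lg:
                    lg[key] = tuple(lg[key])
            d["learner_grid"] = LearnerGrid(**lg)
        if "fit_grid" in d and isinstance(d["fit_grid"], dict):
            d["fit_grid"] = FitGrid(**d["fit_grid"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages into ``out_dir`` and write a manifest.

    Stage order: simulate (cohort + trial logs), fit (per-subject posterior,
    accuracy), compare (BIC/AIC vs the fixed-learning-rate model, optional),
    associate (trait selection + correlations for each gamma). Any failure
    aborts with the stage name; outputs of completed stages persist.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    schedule_config = ScheduleConfig(n_trials=config.n_trials) \
        if config.n_trials == 290 else _short_schedule(config.n_trials)

    stage = "simulate"
    try:
        cohort = generate_cohort(
            n_subjects=config.n_subjects,
            schedule_config=schedule_config,
            seed=config.seeds["cohort"],
            learner_grid=config.learner_grid,
        )
        export_cohort(cohort, out / "cohort")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "fit"
    try:
        fits = []
        for j, record in enumerate(cohort.records):
            posterior = fit_subject(record, config.fit_grid, config.learner_grid)
            beliefs = agent_beliefs(
                AgentSpec(params=posterior.point_estimates), record.schedule,
                config.learner_grid)
            trace = policy_trace(posterior.point_estimates, record.schedule, *beliefs)
            fits.append({
                "subject": j,
                "estimates": dataclasses.asdict(posterior.point_estimates),
                "posterior_sds": posterior.posterior_sds,
                "log_evidence": posterior.log_evidence,
                "max_log_likelihood": posterior.max_log_likelihood,
                "predictive_accuracy": predictive_accuracy(record, trace),
            })
        write_json(out / "fits.json", fits)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if config.run_compare:
        stage = "compare"
        try:
            rows = []
            for j, record in enumerate(cohort.records):
                comp = compare_models(
                    record, config.fit_grid, config.learner_grid,
                    rw_grid=FitGrid(points_per_dim=config.rw_grid_points),
                    rw_alpha_points=config.rw_alpha_points,
                )
                rows.append({
                    "subject": j,
                    "bic": {t: f.bic for t, f in comp.fits.items()},
                    "aic": {t: f.aic for t, f in comp.fits.items()},
                    "preferred_by_bic": comp.preferred_by_bic,
                    "preferred_by_aic": comp.preferred_by_aic,
                })
            summary = {
                "per_subject": rows,
                "n_bic_prefers_bayes": sum(r["preferred_by_bic"] == BAYES_TAG
                                           for r in rows),
                "n_aic_prefers_bayes": sum(r["preferred_by_aic"] == BAYES_TAG
                                           for r in rows),
            }
            write_json(out / "comparison.json", summary)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "associate"
    try:
        traits_path = out / "cohort" / "traits.tsv"
        if not traits_path.exists():
            raise FileNotFoundError(f"missing input {traits_path}")
        import pandas as pd
        traits = pd.read_csv(traits_path, sep="\t").set_index("subject")
        traits = traits[list(TRAIT_NAMES)]
        fitted = {
            "gamma_social": np.array([f["estimates"]["gamma_social"] for f in fits]),
            "gamma_reward_history": np.array(
                [f["estimates"]["gamma_reward_history"] for f in fits]),
        }
        for param, values in fitted.items():
            result = associate(
                traits, values, target=param,
                n_bootstrap_select=config.n_bootstrap_select,
                n_bootstrap_corr=config.n_bootstrap_corr,
                seed=config.seeds["select"],
            )
            write_json(out / f"association_{param}.json", {
                "target": result.target,
                "selected": list(result.optimal_model.selected),
                "fraction": result.optimal_model.fraction,
                "coefficients": result.optimal_model.coefficients,
                "correlations": {k: dataclasses.asdict(v)
                                 for k, v in result.correlations.items()},
                "normality": {k: {"statistic": s, "p": p}
                              for k, (s, p) in result.normality.items()},
            })
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    from .choice_model import PROB_EPS
    from .inference import LL_EPS
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seeds": config.seeds,
        "defaults_in_effect": {
            "probability_clamp_eps": PROB_EPS,
            "likelihood_floor_eps": LL_EPS,
            "fit_prior": "log-uniform over the grid",
            "learner_grid": dataclasses.asdict(config.learner_grid),
            "fit_grid": dataclasses.asdict(config.fit_grid),
        },
        "checksums": {str(p.relative_to(out)): _checksum(p) for p in files},
    }
    write_json(out / "manifest.json", manifest)
    return out


def _short_schedule(n_trials: int) -> ScheduleConfig:
    """Scale the default block structure to a non-standard session length."""
    default = ScheduleConfig()
    def scale(blocks):
        lengths = np.array([b[0] for b in blocks], dtype=float)
        scaled = np.maximum(1, np.round(lengths * n_trials / lengths.sum())).astype(int)
        scaled[-1] += n_trials - scaled.sum()
        return tuple((int(n), p) for n, (_, p) in zip(scaled, blocks))
    return ScheduleConfig(
        n_trials=n_trials,
        reward_prob_blocks=scale(default.reward_prob_blocks),
        advice_fidelity_blocks=scale(default.advice_fidelity_blocks),
    )
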