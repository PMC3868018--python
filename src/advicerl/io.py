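"""File formats: trial logs, belief/trace tables, trait tables, result JSON.

Canonical tabular dialect is TSV (UTF-8, Unix newlines); structured results
are JSON with floats at 12 significant digits. Trial indices are 1-based in
files, 0-based in memory. Colours are encoded ``G``/``B``; binary flags
``0``/``1``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schedules import GREEN, BLUE, TrialSchedule, OutcomeSequences, extract_outcomes
from .learners import BeliefTrajectory
from .choice_model import ChoicePolicyTrace
from .simulate import ChoiceRecord, SyntheticCohort

TRIAL_LOG_COLUMNS = ["trial", "r_green", "r_blue", "advice", "correct",
                     "choice", "reward_outcome", "advice_outcome"]


class TrialLogError(ValueError):
    """Malformed trial-log file; message carries the offending line number."""


def write_trial_log(path, schedule: TrialSchedule,
                    record: ChoiceRecord | None = None) -> None:
    """Write a schedule (and optional choices) in the trial-log TSV format."""
    outcomes = extract_outcomes(schedule)
    n = schedule.n_trials
    choice = record.choices if record is not None else np.full(n, "", dtype=object)
    df = pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "r_green": schedule.r_green,
        "r_blue": schedule.r_blue,
        "advice": schedule.advice,
        "correct": schedule.correct,
        "choice": choice,
        "reward_outcome": outcomes.reward_outcomes,
        "advice_outcome": outcomes.advice_outcomes,
    })
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _fail(row: int, message: str) -> None:
    # +2: one for the header line, one for 1-based file lines
    raise TrialLogError(f"line {row + 2}: {message}")


def read_trial_log(path) -> tuple[TrialSchedule, ChoiceRecord | None]:
    """Parse and validate a trial-log TSV.

    The latent probabilities are not part of the on-disk format (they are
    unobservable in real data) and come back as NaN. Returns ``(schedule,
    record)``; ``record`` is None when the choice column is empty.
    """
    df = pd.read_csv(path, sep="\t", dtype={"choice": "string"})
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise TrialLogError(f"missing columns: {sorted(missing)}")
    n = len(df)
    trials = df["trial"].to_numpy()
    for i in range(n):
        if trials[i] != i + 1:
            _fail(i, f"trial index {trials[i]}, expected {i + 1} "
                     "(1-based, consecutive)")
    for col in ("r_green", "r_blue"):
        vals = df[col].to_numpy()
        bad = np.where(vals < 1)[0]
        if len(bad):
            _fail(int(bad[0]), f"{col} = {vals[bad[0]]} out of range (must be >= 1)")
    for col in ("advice", "correct"):
        vals = df[col].to_numpy()
        bad = np.where(~np.isin(vals, (GREEN, BLUE)))[0]
        if len(bad):
            _fail(int(bad[0]), f"bad colour code {vals[bad[0]]!r} in {col!r}")
    for col in ("reward_outcome", "advice_outcome"):
        vals = df[col].to_numpy()
        bad = np.where(~np.isin(vals, (0, 1)))[0]
        if len(bad):
            _fail(int(bad[0]), f"{col} must be 0/1, got {vals[bad[0]]}")

    correct = df["correct"].to_numpy(dtype="U1")
    reward_outcome = df["reward_outcome"].to_numpy()
    advice = df["advice"].to_numpy(dtype="U1")
    advice_outcome = df["advice_outcome"].to_numpy()
    derived_reward = (correct == GREEN).astype(int)
    bad = np.where(derived_reward != reward_outcome)[0]
    if len(bad):
        _fail(int(bad[0]), "reward_outcome inconsistent with correct colour")
    derived_advice = (advice == correct).astype(int)
    bad = np.where(derived_advice != advice_outcome)[0]
    if len(bad):
        _fail(int(bad[0]), "advice_outcome inconsistent with advice/correct")

    schedule = TrialSchedule(
        p_green_true=np.full(n, np.nan),
        p_social_true=np.full(n, np.nan),
        r_green=df["r_green"].to_numpy(dtype=np.int64),
        r_blue=df["r_blue"].to_numpy(dtype=np.int64),
        correct=correct,
        advice=advice,
    )
    choices = df["choice"].fillna("").to_numpy(dtype="U1")
    if (choices == "").all():
        return schedule, None
    bad = np.where(~np.isin(choices, (GREEN, BLUE)))[0]
    if len(bad):
        _fail(int(bad[0]), f"bad choice code {choices[bad[0]]!r}")
    return schedule, ChoiceRecord(choices=choices, schedule=schedule)


def write_beliefs(path, trajectory: BeliefTrajectory) -> None:
    """Belief trajectory TSV: ``trial  estimate  spread  learner``."""
    pd.DataFrame({
        "trial": np.arange(1, len(trajectory) + 1),
        "estimate": trajectory.estimates,
        "spread": trajectory.spreads,
        "learner": trajectory.learner_tag,
    }).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_trace(path, trace: ChoicePolicyTrace) -> None:
    """Policy trace TSV with the model's per-trial intermediate quantities."""
    pd.DataFrame({
        "trial": np.arange(1, len(trace) + 1),
        "p_hat_social": trace.p_hat_social,
        "p_hat_green": trace.p_hat_green,
        "q_hat": trace.q_hat,
        "v_green": trace.v_green,
        "v_blue": trace.v_blue,
        "p_green_choice": trace.p_choose_green,
    }).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _round_floats(dataclasses.asdict(obj), sig)
    return obj


def write_json(path, payload) -> None:
    """Serialise a (possibly nested/dataclass) result to JSON.

    Floats are written at 12 significant digits for cross-platform stability.
    """
    Path(path).write_text(json.dumps(_round_floats(payload), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def export_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort: one trial log per subject, traits.tsv, ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, record in enumerate(cohort.records):
        write_trial_log(out / f"subject_{j:03d}.tsv", record.schedule, record)
    traits = cohort.traits.copy()
    traits.insert(0, "subject", traits.index)
    traits.to_csv(out / "traits.tsv", sep="\t", index=False, lineterminator="\n")
    ground_truth = {
        "ground_truth_map": cohort.ground_truth_map,
        "noise_sd": cohort.noise_sd,
        "trait_means_sds": {k: list(v) for k, v in cohort.trait_means_sds.items()},
        "specs": [
            {
                "gamma_social": s.params.gamma_social,
                "gamma_reward_history": s.params.gamma_reward_history,
                "beta": s.params.beta,
                "learner_tag": s.learner_tag,
                "seed": s.seed,
            }
            for s in cohort.specs
        ],
    }
    write_json(out / "ground_truth.json", ground_truth)
    return out
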