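"""Synthetic experiment generator.

Emulates the three reaching-experiment designs end to end: per-condition
blocks of 2-D endpoints produced by the generative model, baseline-scaled
target widths, and (for the third design) a Parkinson's-like group whose
reinforcement-update gain alpha is reduced while everything else is shared
with the age-matched control group.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model_core import (
    ALPHA_NAMES,
    CONDITIONS,
    PARAM_NAMES,
    SIGMA_NAMES,
    ModelParams,
    ModelSpec,
    MODEL_SPECS,
    TargetGeometry,
    TrialSeries,
    session_seeds,
    simulate_session,
)

__all__ = [
    "WIDTH_SCALE",
    "ExperimentDesign",
    "EXP1",
    "EXP2",
    "EXP3",
    "DESIGNS",
    "design_from_id",
    "CohortConfig",
    "compute_target_width",
    "make_pd_cohort_config",
    "generate_experiment",
]

#: Minor-axis width as a fraction of baseline lateral (minor-axis) SD.
WIDTH_SCALE = 0.65


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial counts, condition sets and groups of one experiment design."""

    design_id: str
    conditions: tuple[str, ...]
    trials_per_condition: int
    groups: dict[str, int]  # group label -> number of participants

    def __post_init__(self) -> None:
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition(s) {sorted(unknown)}")
        if self.trials_per_condition < 2:
            raise ValueError("trials_per_condition must be >= 2")
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise ValueError("each group needs at least one participant")


#: Two conditions of 200 trials in 36 young participants.
EXP1 = ExperimentDesign("exp1", ("reinforcement", "error"), 200, {"young": 36})
#: Three conditions of 200 trials in 36 young participants.
EXP2 = ExperimentDesign(
    "exp2", ("reinforcement", "error", "reinforcement_and_error"), 200, {"young": 36}
)
#: Three conditions of 100 trials; 12 age-matched controls and 10
#: participants in the reduced-alpha (Parkinson's-like) group.
EXP3 = ExperimentDesign(
    "exp3",
    ("reinforcement", "error", "reinforcement_and_error"),
    100,
    {"control": 12, "parkinsons": 10},
)

DESIGNS = {"exp1": EXP1, "exp2": EXP2, "exp3": EXP3}


def design_from_id(design_id: str) -> ExperimentDesign:
    try:
        return DESIGNS[design_id]
    except KeyError:
        raise ValueError(f"unknown design {design_id!r}") from None


@dataclass(frozen=True)
class CohortConfig:
    """Generating model and parameters per group, plus optional jitter.

    ``jitter_sd`` maps parameter names to the SD of a per-participant
    truncated-normal perturbation (defaults to none: the model holds
    parameters constant across simulees).  ``baseline_trials`` > 0 switches
    the target-width rule from the closed-form 0.65 x sigma_M_x to an
    estimate from a simulated no-feedback baseline block of that length.
    """

    params_by_group: dict[str, ModelParams]
    spec: ModelSpec = MODEL_SPECS[1]
    jitter_sd: dict[str, float] = field(default_factory=dict)
    baseline_trials: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.jitter_sd) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown jitter parameter(s) {sorted(unknown)}")
        if any(sd < 0 for sd in self.jitter_sd.values()):
            raise ValueError("jitter SDs must be >= 0")


def compute_target_width(baseline_sd: float) -> float:
    """Minor-axis target width from baseline lateral variability (cm).

    The width is proportional to the participant's lateral endpoint SD over
    the final baseline trials: ``0.65 * sigma``.
    """
    if not np.isfinite(baseline_sd) or baseline_sd <= 0:
        raise ValueError("baseline SD must be positive")
    return WIDTH_SCALE * float(baseline_sd)


def make_pd_cohort_config(
    control_config: CohortConfig, alpha_scale: float
) -> CohortConfig:
    """Scale every group's reinforcement gains by ``alpha_scale``, all else shared."""
    if not 0.0 <= alpha_scale <= 1.0:
        raise ValueError("alpha_scale must lie in [0, 1]")
    scaled = {
        group: params.replace(
            **{name: getattr(params, name) * alpha_scale for name in ALPHA_NAMES}
        )
        for group, params in control_config.params_by_group.items()
    }
    return replace(control_config, params_by_group=scaled)


def _jittered(params: ModelParams, jitter_sd: dict[str, float], rng) -> ModelParams:
    if not jitter_sd:
        return params
    changes = {}
    for name, sd in jitter_sd.items():
        value = getattr(params, name) + sd * rng.standard_normal()
        if name in SIGMA_NAMES:
            # tiny floor keeps the baseline width rule defined
            changes[name] = max(value, 1e-6)
        else:
            changes[name] = float(np.clip(value, 0.0, 1.0))
    return params.replace(**changes)


def _baseline_width(params: ModelParams, n_trials: int, seed: int) -> float:
    """Width from a simulated no-feedback baseline block.

    Baseline reaches precede any reinforcement manipulation, so endpoints
    are aim plus motor noise only; the width rule uses the lateral SD of
    the block.
    """
    rng = np.random.default_rng(seed)
    x = params.sigma_M_x * rng.standard_normal(n_trials)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate baseline block (zero lateral variability)")
    return compute_target_width(sd)


def generate_experiment(
    design: ExperimentDesign,
    config: CohortConfig,
    seed: int,
) -> tuple[list[TrialSeries], dict]:
    """Generate one full synthetic experiment.

    Per participant: a derived sub-seed (shared across conditions), an
    optionally jittered parameter set, a baseline-scaled target width, and
    one TrialSeries per condition starting from a re-centered aim (washout
    between conditions leaves no carry-over).  A manifest records seeds,
    widths and the counterbalanced condition order per participant.

    The dataset is a pure function of (design, config, seed).
    """
    master = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(master.spawn(1)[0])
    series_out: list[TrialSeries] = []
    manifest: dict = {
        "design_id": design.design_id,
        "seed": int(seed),
        "spec_model_id": config.spec.model_id,
        "participants": [],
    }
    counter = 0
    for group in sorted(design.groups):
        group_params = config.params_by_group[group]
        n = design.groups[group]
        seeds = session_seeds(int(master.generate_state(1)[0] + counter) % 2**31, n)
        for i in range(n):
            pid = f"{group}{i:03d}"
            params = _jittered(group_params, config.jitter_sd, jitter_rng)
            if config.baseline_trials > 0:
                width = _baseline_width(
                    params, config.baseline_trials, int(seeds[i]) ^ 0x5F5F
                )
            else:
                width = compute_target_width(params.sigma_M_x)
            geometry = TargetGeometry(minor_width=width)
            # counterbalanced block order, recorded but with no generative effect
            order = tuple(
                np.roll(np.arange(len(design.conditions)), i % len(design.conditions))
            )
            for condition in design.conditions:
                series_out.append(
                    simulate_session(
                        params,
                        config.spec,
                        condition,
                        geometry,
                        design.trials_per_condition,
                        int(seeds[i]),
                        participant_id=pid,
                        group=group,
                        experiment=design.design_id,
                    )
                )
            manifest["participants"].append(
                {
                    "participant_id": pid,
                    "group": group,
                    "seed": int(seeds[i]),
                    "minor_width_cm": width,
                    "condition_order": [design.conditions[j] for j in order],
                }
            )
        counter += 1
    return series_out, manifest
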