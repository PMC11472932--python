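"""Generative model of trial-by-trial reach endpoints under reinforcement and error feedback.

The model describes reaching to a long rectangular target whose major axis is
task-redundant (any endpoint along it is equally successful) and whose minor
axis is task-relevant.  Coordinates are target-frame throughout: x is the
minor/task-relevant axis, y the major/task-redundant axis, origin at the
target center, units cm.

On every trial the endpoint is the latent movement aim plus motor noise, plus
exploratory noise that is injected only after an unsuccessful trial.  After a
success that followed a miss, the aim is updated by a fraction ``alpha`` of the
exploratory deviation (a reinforcement process); when positional error
feedback is available, the aim is additionally corrected by ``beta_aim``
toward the previously intended aim and by ``beta_target`` toward the target
center.  The general model carries all ten parameters; the eight reduced
variants zero specific error-correction gains.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._kernel import simulate_paths

__all__ = [
    "PARAM_NAMES",
    "SIGMA_NAMES",
    "ALPHA_NAMES",
    "BETA_NAMES",
    "CONDITIONS",
    "ModelParams",
    "ModelSpec",
    "MODEL_SPECS",
    "TargetGeometry",
    "TrialState",
    "TrialRecord",
    "TrialSeries",
    "REFERENCE_PARAMS",
    "apply_condition",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "session_seeds",
]

#: Canonical parameter order used everywhere a flat vector is exchanged.
PARAM_NAMES = (
    "sigma_M_x",
    "sigma_M_y",
    "sigma_E_x",
    "sigma_E_y",
    "alpha_x",
    "alpha_y",
    "beta_aim_x",
    "beta_aim_y",
    "beta_target_x",
    "beta_target_y",
)
SIGMA_NAMES = PARAM_NAMES[:4]
ALPHA_NAMES = ("alpha_x", "alpha_y")
BETA_NAMES = ("beta_aim_x", "beta_aim_y", "beta_target_x", "beta_target_y")

#: Feedback conditions: reinforcement gives only the binary hit/miss signal
#: (no error correction acts), error gives only cursor feedback (no
#: reinforcement aim update acts), reinforcement_and_error gives both.
CONDITIONS = ("reinforcement", "error", "reinforcement_and_error")


@dataclass(frozen=True)
class ModelParams:
    """The ten generative parameters.

    Noise terms are standard deviations in cm; gains are unitless fractions
    in [0, 1].
    """

    sigma_M_x: float
    sigma_M_y: float
    sigma_E_x: float
    sigma_E_y: float
    alpha_x: float
    alpha_y: float
    beta_aim_x: float
    beta_aim_y: float
    beta_target_x: float
    beta_target_y: float

    def __post_init__(self) -> None:
        for name in SIGMA_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite SD >= 0, got {v!r}")
        for name in ALPHA_NAMES + BETA_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ModelParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (10,):
            raise ValueError("expected 10 parameter values")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelSpec:
    """One member of the nine-model family: a mask of gains fixed to zero."""

    model_id: int
    zeroed_params: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.zeroed_params - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s) in spec: {sorted(unknown)}")

    @property
    def n_free(self) -> int:
        return len(PARAM_NAMES) - len(self.zeroed_params)

    @property
    def free_params(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.zeroed_params)


def _spec(model_id: int, *zeroed: str) -> ModelSpec:
    return ModelSpec(model_id, frozenset(zeroed))


#: The nine-model family.  Model 1 is the general model; the reduced variants
#: remove specific error-correction gains.  Model 4 (no correction toward the
#: target center along the redundant major axis) is the reported best fit.
MODEL_SPECS: dict[int, ModelSpec] = {
    1: _spec(1),
    2: _spec(2, "beta_target_x", "beta_target_y"),
    3: _spec(3, "beta_aim_x", "beta_aim_y"),
    4: _spec(4, "beta_target_y"),
    5: _spec(5, "beta_aim_y"),
    6: _spec(6, "beta_aim_x"),
    7: _spec(7, "beta_target_x"),
    8: _spec(8, "beta_target_x", "beta_aim_y"),
    9: _spec(9, "beta_aim_x", "beta_target_y"),
}

#: Reference parameter set used for the a priori cohort predictions
#: (general-model simulations of all three experiment designs).
REFERENCE_PARAMS = ModelParams(
    sigma_M_x=0.37,
    sigma_M_y=0.49,
    sigma_E_x=0.38,
    sigma_E_y=0.88,
    alpha_x=0.99,
    alpha_y=0.99,
    beta_aim_x=0.15,
    beta_aim_y=0.25,
    beta_target_x=0.13,
    beta_target_y=0.01,
)


@dataclass(frozen=True)
class TargetGeometry:
    """Rectangular target centered at the origin of the target frame.

    ``major_length`` spans the task-redundant y axis (12 cm in the task this
    model describes); ``minor_width`` spans the task-relevant x axis and is
    scaled to each participant's baseline lateral variability.
    """

    minor_width: float
    major_length: float = 12.0

    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.minor_width <= 0 or self.major_length <= 0:
            raise ValueError("target extents must be positive")
        if self.center != (0.0, 0.0):
            raise ValueError("target frame places the target center at the origin")

    def contains(self, x, y):
        """Hit test (boundary inclusive); accepts scalars or arrays."""
        return (np.abs(x) <= self.minor_width / 2.0) & (
            np.abs(y) <= self.major_length / 2.0
        )


@dataclass(frozen=True)
class TrialState:
    """Latent state entering a trial: current aim and last trial's outcome."""

    aim: tuple[float, float] = (0.0, 0.0)
    prev_reward: int = 1

    def __post_init__(self) -> None:
        if self.prev_reward not in (0, 1):
            raise ValueError("prev_reward must be 0 or 1")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based
    x: float
    y: float
    aim_x: float
    aim_y: float
    reward: int


@dataclass
class TrialSeries:
    """Ordered record of one participant's trials in one feedback condition."""

    participant_id: str
    group: str
    condition: str
    records: list[TrialRecord]
    experiment: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for i, rec in enumerate(self.records, start=1):
            if rec.trial_index != i:
                raise ValueError("trial indices must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.records)

    def endpoints(self) -> np.ndarray:
        """(n, 2) array of endpoints, columns (x, y)."""
        return np.array([(r.x, r.y) for r in self.records], dtype=float)

    def rewards(self) -> np.ndarray:
        return np.array([r.reward for r in self.records], dtype=np.int8)

    def aims(self) -> np.ndarray:
        return np.array([(r.aim_x, r.aim_y) for r in self.records], dtype=float)


def apply_condition(
    params: ModelParams, condition: str, spec: ModelSpec
) -> ModelParams:
    """Return the effective parameters for a model variant in a condition.

    The variant's zeroed gains are set to 0 first; then the feedback
    condition forces whole processes off: with reinforcement-only feedback
    no error-correction acts (all beta = 0), with error-only feedback no
    reinforcement aim update acts (all alpha = 0).  Idempotent.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    changes = {name: 0.0 for name in spec.zeroed_params}
    if condition == "reinforcement":
        changes.update({name: 0.0 for name in BETA_NAMES})
    elif condition == "error":
        changes.update({name: 0.0 for name in ALPHA_NAMES})
    return params.replace(**changes)


def simulate_trial(
    state: TrialState,
    params: ModelParams,
    geometry: TargetGeometry,
    noise_draws: Sequence[float],
) -> tuple[TrialRecord, TrialState]:
    """Advance the recursion by one trial from externally supplied deviates.

    ``noise_draws`` are four standard-normal deviates in the fixed order
    (motor-x, motor-y, explore-x, explore-y).  Exploratory noise enters only
    if the previous trial missed; on a rewarded trial the aim absorbs a
    fraction alpha of that exploratory deviation, and the error-correction
    gains pull the aim toward the previous aim and the target center.
    """
    z = np.asarray(noise_draws, dtype=float)
    if z.shape != (4,) or not np.all(np.isfinite(z)):
        raise ValueError("noise_draws must be four finite standard-normal deviates")
    aim_x, aim_y = state.aim
    miss_gate = 1 - state.prev_reward
    e_x = miss_gate * params.sigma_E_x * z[2]
    e_y = miss_gate * params.sigma_E_y * z[3]
    x = aim_x + params.sigma_M_x * z[0] + e_x
    y = aim_y + params.sigma_M_y * z[1] + e_y
    r = int(geometry.contains(x, y))
    new_aim_x = (
        aim_x
        + r * params.alpha_x * e_x
        - params.beta_aim_x * (x - aim_x)
        - params.beta_target_x * x
    )
    new_aim_y = (
        aim_y
        + r * params.alpha_y * e_y
        - params.beta_aim_y * (y - aim_y)
        - params.beta_target_y * y
    )
    record = TrialRecord(
        trial_index=1, x=x, y=y, aim_x=aim_x, aim_y=aim_y, reward=r
    )
    return record, TrialState(aim=(new_aim_x, new_aim_y), prev_reward=r)


def _simulate_arrays(
    params: ModelParams,
    n_trials: int,
    geometry: TargetGeometry,
    seed: int,
    r0: int,
):
    """Single-individual run through the batched kernel."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_trials, 4, 1))
    theta = params.as_array()[:, None]
    hw = np.array([geometry.minor_width / 2.0])
    hl = np.array([geometry.major_length / 2.0])
    r0_arr = np.array([r0], dtype=np.int8)
    return simulate_paths(z, theta, hw, hl, r0_arr)


def simulate_session(
    params: ModelParams,
    spec: ModelSpec,
    condition: str,
    geometry: TargetGeometry,
    n_trials: int,
    seed: int,
    r0: int = 1,
    participant_id: str = "sim",
    group: str = "sim",
    experiment: str = "",
) -> TrialSeries:
    """Simulate one participant's condition block.

    The aim starts at the target center and the pre-first-trial outcome flag
    defaults to a success (``r0=1``, no exploratory noise on trial 1).  The
    four deviates per trial are drawn in a fixed order regardless of gating,
    so conditions simulated from one seed share their random stream.
    Deterministic given ``seed``.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if r0 not in (0, 1):
        raise ValueError("r0 must be 0 or 1")
    eff = apply_condition(params, condition, spec)
    x, y, aim_x, aim_y, reward = _simulate_arrays(eff, n_trials, geometry, seed, r0)
    records = [
        TrialRecord(
            trial_index=t + 1,
            x=float(x[t, 0]),
            y=float(y[t, 0]),
            aim_x=float(aim_x[t, 0]),
            aim_y=float(aim_y[t, 0]),
            reward=int(reward[t, 0]),
        )
        for t in range(n_trials)
    ]
    return TrialSeries(
        participant_id=participant_id,
        group=group,
        condition=condition,
        records=records,
        experiment=experiment,
    )


def session_seeds(seed: int, n_individuals: int) -> np.ndarray:
    """Reproducible per-individual sub-seeds (< 2**31), shared across conditions."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_individuals) % np.uint32(2**31)


def simulate_cohort(
    params: ModelParams,
    spec: ModelSpec,
    conditions: Iterable[str],
    geometry: TargetGeometry,
    n_individuals: int,
    n_trials: int,
    seed: int,
    r0: int = 1,
    group: str = "sim",
    experiment: str = "",
) -> list[TrialSeries]:
    """Simulate ``n_individuals`` independent participants per condition.

    Each individual gets one derived sub-seed used for every condition, so
    cross-condition contrasts are seed-aligned (conditions differ only in
    which processes act on a common random stream).
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("conditions must be non-empty")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    seeds = session_seeds(seed, n_individuals)
    out: list[TrialSeries] = []
    for i, sub in enumerate(seeds):
        for condition in conditions:
            out.append(
                simulate_session(
                    params,
                    spec,
                    condition,
                    geometry,
                    n_trials,
                    int(sub),
                    r0=r0,
                    participant_id=f"{group}{i:03d}",
                    group=group,
                    experiment=experiment,
                )
            )
    return out
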