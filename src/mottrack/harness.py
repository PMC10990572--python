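"""Experiment-reproduction harness.

Presets for the classic MOT experiments the model reproduces, the
empirical-to-simulation speed conversions, block runners with seeded
replication, a bisection search for speed thresholds, the adaptive
calibration staircase, and exhaustive grid-search parameter fitting against
a reference accuracy curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (EnvironmentConfig, simulate_trajectory,
                       generate_shell_game_trial, mean_axis_step_length)
from .model import ModelParams, TrialResult, run_model_on_trajectory

__all__ = [
    "ConversionSpec",
    "Preset",
    "BlockResult",
    "ThresholdResult",
    "StaircaseState",
    "FitResult",
    "tracking_accuracy",
    "empirical_to_sim_sigma",
    "experiment_preset",
    "PRESET_NAMES",
    "dissociation_preset",
    "run_trial",
    "run_block",
    "speed_threshold",
    "staircase_next",
    "staircase_converged",
    "run_staircase",
    "accuracy_vs_targets_curve",
    "grid_fit",
    "trial_seeds",
]

#: Conversion factor between the OU noise scale and the mean per-axis
#: displacement per update at k = 0.0005, lam = 0.9 (measured; see
#: mean_axis_step_length).  Its reciprocal (0.555) appears in the OU speed
#: conversion.
OU_STEP_FACTOR = 1.8


def trial_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit child seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def tracking_accuracy(reported_objects: Sequence[int],
                      target_set: Sequence[int]) -> float:
    """k/n with k the number of distinct targets among the reports; missing
    reports count against k."""
    targets = set(int(t) for t in target_set)
    n = len(targets)
    if n == 0:
        raise ValueError("at least one target required")
    k = len(set(int(r) for r in reported_objects) & targets)
    return k / n


@dataclass(frozen=True)
class ConversionSpec:
    """Inputs of the empirical-to-simulation speed conversion.

    theta : visual angle of the MOT window (degrees)
    d     : empirical object speed (degrees / second)
    s     : grid side (cells)
    eta   : simulation updates per second
    """

    theta: float
    d: float
    s: float
    eta: float
    dynamics_kind: str = "constant_speed"

    def __post_init__(self):
        if min(self.theta, self.d, self.s, self.eta) <= 0:
            raise ValueError("all conversion inputs must be positive")


def empirical_to_sim_sigma(spec: ConversionSpec) -> float:
    """Simulation speed parameter sigma (pixels/update) equivalent to an
    empirical speed, obtained by equating window-crossing times.

    Constant speed:  sigma = s * d / (eta * theta).
    OU:              sigma = (1/1.8) * s * d / (eta * theta), because one OU
    update covers on average 1.8 * sigma pixels per axis.
    """
    sigma = spec.s * spec.d / (spec.eta * spec.theta)
    if spec.dynamics_kind == "ou":
        sigma /= OU_STEP_FACTOR
    elif spec.dynamics_kind != "constant_speed":
        raise ValueError("dynamics_kind must be 'constant_speed' or 'ou'")
    return sigma


@dataclass(frozen=True)
class Preset:
    """A named experiment configuration: environment, model parameters, and
    reproduction metadata (tabulated speed range, target counts to sweep).
    The object counts in ``meta`` are assumptions where the original reports
    omit them, and are overridable."""

    name: str
    env: EnvironmentConfig
    params: ModelParams
    sigma_range: tuple[float, float]
    target_counts: tuple[int, ...]
    notes: str = ""


def _preset_table() -> dict[str, Preset]:
    presets = {}
    presets["PS1988"] = Preset(
        name="PS1988",
        env=EnvironmentConfig(
            dynamics_kind="constrained_ou", sigma=18.0, arena=(360.0, 360.0),
            updates_per_second=2.5, n_updates=25, min_distance=15.0,
            n_targets=3, n_objects=10),
        params=ModelParams(f_loc=28.0, f_u=10.0, c_e=math.inf, nob=math.inf,
                           capacity=8),
        sigma_range=(18.0, 18.0),
        target_counts=(1, 2, 3, 4, 5),
        notes="360x360 grid, 25 updates over 10 s; 10 objects assumed.")
    presets["AF2007"] = Preset(
        name="AF2007",
        env=EnvironmentConfig(
            dynamics_kind="constant_speed", sigma=1.0, arena=(720.0, 720.0),
            updates_per_second=60.0, n_updates=300, min_distance=80.0,
            n_targets=4, n_objects=8),
        params=ModelParams(f_loc=30.0, f_u=3.0, c_e=math.inf, nob=24.0,
                           capacity=8),
        sigma_range=(0.1, 6.0),
        target_counts=(1, 2, 3, 4, 5, 6, 7, 8),
        notes="constant speed, 300 updates over 5 s; equal numbers of "
              "targets and distractors assumed (n_objects = 2 n).")
    presets["SV2016"] = Preset(
        name="SV2016",
        env=EnvironmentConfig(
            dynamics_kind="ou", sigma=2.0, arena=(720.0, 720.0),
            updates_per_second=30.0, n_updates=150, min_distance=0.0,
            n_targets=3, n_objects=12),
        params=ModelParams(f_loc=30.0, f_u=10.0, c_e=math.inf, nob=60.0,
                           capacity=8),
        sigma_range=(1.3, 5.4),
        target_counts=(1, 2, 3, 4, 5, 6),
        notes="unconstrained OU (objects may overlap), 150 updates over 5 s; "
              "12 objects assumed.")
    presets["FR2008-small"] = Preset(
        name="FR2008-small",
        env=EnvironmentConfig(
            dynamics_kind="constant_speed", sigma=1.0, arena=(180.0, 180.0),
            updates_per_second=90.0, n_updates=540, min_distance=24.0,
            n_targets=4, n_objects=8),
        params=ModelParams(f_loc=17.0, f_u=10.0, c_e=math.inf, nob=math.inf,
                           capacity=8),
        sigma_range=(0.45, 2.25),
        target_counts=(1, 2, 3, 4),
        notes="small display; 8 objects assumed.")
    presets["FR2008-large"] = Preset(
        name="FR2008-large",
        env=EnvironmentConfig(
            dynamics_kind="constant_speed", sigma=4.0, arena=(720.0, 720.0),
            updates_per_second=90.0, n_updates=540, min_distance=96.0,
            n_targets=4, n_objects=8),
        params=ModelParams(f_loc=16.0, f_u=10.0, c_e=math.inf, nob=math.inf,
                           capacity=8),
        sigma_range=(1.8, 9.0),
        target_counts=(1, 2, 3, 4),
        notes="large display; 8 objects assumed.")
    presets["Exp1"] = Preset(
        name="Exp1",
        env=EnvironmentConfig(
            dynamics_kind="ou", sigma=2.0, arena=(720.0, 720.0),
            updates_per_second=30.0, n_updates=150, min_distance=0.0,
            n_targets=4, n_objects=14),
        params=ModelParams(f_loc=30.0, f_u=10.0, c_e=math.inf, nob=52.0,
                           f_corr=0.4, capacity=8),
        sigma_range=(1.3, 5.4),
        target_counts=(1, 2, 3, 4, 5, 6, 7, 8),
        notes="14 objects, 5 s trials; model parameters are the best-fit "
              "values (f_loc=30, nob=52, f_corr=0.4).")
    presets["Exp2"] = Preset(
        name="Exp2",
        env=EnvironmentConfig(
            dynamics_kind="shell_game", sigma=4.0, arena=(1080.0, 720.0),
            updates_per_second=60.0, n_updates=300, min_distance=120.0,
            n_targets=2, n_objects=3),
        params=ModelParams(f_loc=30.0, f_u=10.0, c_e=math.inf, nob=52.0,
                           f_corr=0.0, capacity=8),
        sigma_range=(0.5, 18.0),
        target_counts=(2, 3, 4),
        notes="shell-game trials with one distractor "
              "(n_objects = n_targets + 1), 120-px separation floor.")
    return presets


_PRESETS = _preset_table()
PRESET_NAMES = tuple(_PRESETS)


def experiment_preset(name: str) -> Preset:
    """Named experiment configuration; unknown names raise with the list of
    valid presets."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


def dissociation_preset(n_targets: int = 4, n_objects: int = 8,
                        sigma: float = 1.25,
                        duration_s: float = 10.0) -> Preset:
    """Configuration of the tracking-versus-identity dissociation runs:
    unconstrained OU motion (objects may cross paths) on a 720x720 grid at
    30 updates/s, with the whole-grid search bound and f_corr = 0, so that
    identity errors accumulate while tracking degrades more slowly."""
    env = EnvironmentConfig(
        dynamics_kind="ou", sigma=sigma, arena=(720.0, 720.0),
        updates_per_second=30.0, n_updates=int(round(30.0 * duration_s)),
        min_distance=0.0, n_targets=n_targets, n_objects=n_objects)
    params = ModelParams(f_loc=28.0, f_u=10.0, c_e=math.inf, nob=math.inf,
                         f_corr=0.0, capacity=max(8, n_targets))
    return Preset(name="dissociation", env=env, params=params,
                  sigma_range=(sigma, sigma),
                  target_counts=(n_targets,))


# ---------------------------------------------------------------------------
# Replication loop
# ---------------------------------------------------------------------------

def run_trial(env: EnvironmentConfig, params: ModelParams,
              seed: int) -> TrialResult:
    """One seeded trial: simulate (or generate) the stimulus, run the
    tracker on it."""
    traj_seed, model_seed = (int(s) for s in trial_seeds(seed, 2))
    if env.dynamics_kind == "shell_game":
        gen_rng = np.random.default_rng(traj_seed)
        screening = replace(params, f_corr=0.0)
        traj = generate_shell_game_trial(env, screening, gen_rng)
    else:
        traj = simulate_trajectory(env, traj_seed)
    return run_model_on_trajectory(traj, params, seed=model_seed)


@dataclass
class BlockResult:
    """Per-metric mean and standard error over independent seeded trials."""

    n_trials: int
    mean_tracking: float
    sem_tracking: float
    mean_id: float
    sem_id: float
    results: list[TrialResult] = field(repr=False, default_factory=list)


def run_block(env: EnvironmentConfig, params: ModelParams, n_trials: int,
              seed: int) -> BlockResult:
    """Independent seeded trials of one configuration."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    seeds = trial_seeds(seed, n_trials)
    results = [run_trial(env, params, int(s)) for s in seeds]
    tr = np.array([r.tracking_accuracy for r in results])
    ia = np.array([r.id_accuracy for r in results])
    def sem(x):
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    return BlockResult(
        n_trials=n_trials,
        mean_tracking=float(tr.mean()), sem_tracking=sem(tr),
        mean_id=float(ia.mean()), sem_id=sem(ia),
        results=results)


# ---------------------------------------------------------------------------
# Speed thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    sigma: Optional[float]
    status: str  # "ok" | "below_bracket" | "at_upper_bracket"
    evaluations: list[tuple[float, float]] = field(default_factory=list)


def speed_threshold(env_template: EnvironmentConfig, params: ModelParams,
                    accuracy_target: float, n_trials: int, tolerance: float,
                    seed: int, bracket: tuple[float, float],
                    accuracy_fn: Optional[Callable[[float], float]] = None
                    ) -> ThresholdResult:
    """Largest sigma at which mean tracking accuracy still reaches the
    target, by bisection over the bracket.

    Accuracy is assumed non-increasing in sigma over the bracket.  The same
    trial seeds are reused at every sigma (common random numbers), so the
    empirical accuracy function is deterministic in sigma.  ``accuracy_fn``
    may replace the simulated observer (used for validation against
    closed-form observers).
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    evals: list[tuple[float, float]] = []

    if accuracy_fn is None:
        def accuracy_fn(sigma: float) -> float:
            env = replace(env_template, sigma=sigma)
            return run_block(env, params, n_trials, seed).mean_tracking

    def acc(sigma: float) -> float:
        a = accuracy_fn(sigma)
        evals.append((sigma, a))
        return a

    if acc(hi) >= accuracy_target:
        return ThresholdResult(sigma=hi, status="at_upper_bracket",
                               evaluations=evals)
    if acc(lo) < accuracy_target:
        return ThresholdResult(sigma=None, status="below_bracket",
                               evaluations=evals)
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if acc(mid) >= accuracy_target:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(sigma=lo, status="ok", evaluations=evals)


# ---------------------------------------------------------------------------
# Calibration staircase
# ---------------------------------------------------------------------------

@dataclass
class StaircaseState:
    """History of the speed-calibration staircase.

    sigma moves on a 0.5 lattice within [0.5, 6.0]; it starts at 1.0, is
    reset to 1.0 after any error, and after a correct trial stays, steps up,
    or steps down by 0.5 with probability 1/3 each (clamped at the bounds).
    """

    sigma_history: list[float] = field(default_factory=list)
    correct_history: list[bool] = field(default_factory=list)
    sigma_0: float = 1.0
    sigma_min: float = 0.5
    sigma_max: float = 6.0
    step: float = 0.5

    def record(self, sigma: float, correct: bool) -> None:
        self.sigma_history.append(sigma)
        self.correct_history.append(correct)

    @property
    def current_sigma(self) -> float:
        return self.sigma_history[-1] if self.sigma_history else self.sigma_0


def staircase_next(state: StaircaseState, last_trial_correct: bool,
                   rng: np.random.Generator) -> float:
    """sigma for the next trial given the outcome of the last one."""
    if not last_trial_correct:
        return state.sigma_0
    sigma = state.current_sigma
    move = rng.integers(0, 3)  # 0: down, 1: stay, 2: up
    if move == 0:
        sigma -= state.step
    elif move == 2:
        sigma += state.step
    sigma = min(max(sigma, state.sigma_min), state.sigma_max)
    return round(sigma / state.step) * state.step  # stay on the lattice


def staircase_converged(state: StaircaseState) -> bool:
    """Calibration succeeds once the last 5 trials were all correct with a
    sigma range of at most 0.5."""
    if len(state.correct_history) < 5:
        return False
    if not all(state.correct_history[-5:]):
        return False
    last = state.sigma_history[-5:]
    return max(last) - min(last) <= 0.5 + 1e-9


def run_staircase(env_template: EnvironmentConfig, params: ModelParams,
                  seed: int, max_trials: int = 200,
                  correct_fn: Optional[Callable[[float, int], bool]] = None
                  ) -> StaircaseState:
    """Simulate the calibration staircase with the model as observer.

    A trial is "correct" when every target is tracked (k = n).
    ``correct_fn(sigma, trial_seed)`` may replace the simulated observer.
    Stops at convergence or after ``max_trials``.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState()
    sigma = state.sigma_0
    if correct_fn is None:
        def correct_fn(sig: float, trial_seed: int) -> bool:
            env = replace(env_template, sigma=sig)
            r = run_trial(env, params, trial_seed)
            return r.k == r.n
    for _ in range(max_trials):
        correct = correct_fn(sigma, int(rng.integers(0, 2**31 - 1)))
        state.record(sigma, correct)
        if staircase_converged(state):
            break
        sigma = staircase_next(state, correct, rng)
    return state


# ---------------------------------------------------------------------------
# Accuracy curves and grid-search fitting
# ---------------------------------------------------------------------------

def accuracy_vs_targets_curve(env_template: EnvironmentConfig,
                              params: ModelParams,
                              target_counts: Sequence[int], n_trials: int,
                              seed: int) -> pd.DataFrame:
    """Mean tracking and identity accuracy (with SEM) as a function of the
    number of targets, everything else fixed."""
    rows = []
    for n in target_counts:
        if n < 1:
            raise ValueError("target counts must be at least 1")
        env = replace(env_template, n_targets=n)
        block = run_block(env, params, n_trials, seed)
        rows.append({
            "n_targets": n,
            "tracking_mean": block.mean_tracking,
            "tracking_sem": block.sem_tracking,
            "id_mean": block.mean_id,
            "id_sem": block.sem_id,
        })
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    best_params: dict
    mse: float
    r2: float
    table: pd.DataFrame = field(repr=False, default=None)


def grid_fit(f_loc_range: Sequence[float], nob_range: Sequence[float],
             f_corr_range: Sequence[float],
             env_template: EnvironmentConfig,
             reference_curve: dict[int, float] | pd.Series,
             n_trials: int, seed: int,
             params_template: Optional[ModelParams] = None,
             metric: str = "tracking") -> FitResult:
    """Exhaustive grid search minimising the mean squared error between the
    model's accuracy curve and a reference curve indexed by target count.

    The same seeds are used for every parameter combination (common random
    numbers).  Ties break to the smaller f_loc, then the smaller nob, then
    the smaller f_corr.  r^2 is ``1 - SS_res / SS_tot`` about the reference
    mean (``-inf`` for a constant reference with nonzero residuals).
    """
    if not (len(f_loc_range) and len(nob_range) and len(f_corr_range)):
        raise ValueError("parameter grid must be non-empty")
    ref = pd.Series(dict(reference_curve)).sort_index()
    counts = [int(n) for n in ref.index]
    if params_template is None:
        params_template = ModelParams(f_loc=30.0)
    col = "tracking_mean" if metric == "tracking" else "id_mean"
    rows = []
    best = None
    for f_loc in f_loc_range:
        for nob in nob_range:
            for f_corr in f_corr_range:
                params = replace(params_template, f_loc=float(f_loc),
                                 nob=float(nob), f_corr=float(f_corr))
                curve = accuracy_vs_targets_curve(
                    env_template, params, counts, n_trials, seed)
                model = curve[col].to_numpy()
                resid = model - ref.to_numpy(dtype=float)
                mse = float(np.mean(resid ** 2))
                rows.append({"f_loc": f_loc, "nob": nob, "f_corr": f_corr,
                             "mse": mse})
                key = (mse, f_loc, nob, f_corr)
                if best is None or key < best[0]:
                    best = (key, params, resid)
    _, best_params, resid = best
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((ref.to_numpy(dtype=float) - ref.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else -math.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return FitResult(
        best_params={"f_loc": best_params.f_loc, "nob": best_params.nob,
                     "f_corr": best_params.f_corr},
        mse=float(np.mean(resid ** 2)),
        r2=r2,
        table=pd.DataFrame(rows))
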