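"""Object motion simulators for multiple-object-tracking (MOT) displays.

Three motion regimes are provided, matching the stimulus classes used across
the classic MOT literature:

* **constant-speed** — objects move at a fixed speed and are deflected by an
  inverse-square repulsion from neighbours and walls that come within a
  minimum distance;
* **Ornstein-Uhlenbeck (OU)** — velocities follow a discrete OU recurrence
  with inertia ``lam``, a weak spring ``k`` toward the arena centre, and
  Gaussian innovations of standard deviation ``sigma``;
* **constrained OU** — the OU recurrence with position changes applied only
  when they keep all pairwise distances at or above a minimum.

A fourth generator produces "shell-game" trials: objects travel along
circular arcs so that their spatial sort order changes repeatedly while
their pairwise separation never drops below a floor, which induces identity
confusions without tracking confusions.

All randomness flows through an explicit :class:`numpy.random.Generator`;
the same config and seed always reproduce the same trajectory bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "EnvironmentConfig",
    "WorldState",
    "Trajectory",
    "InvalidConfigError",
    "TrialGenerationError",
    "init_world",
    "ou_step",
    "constrained_ou_step",
    "constant_speed_step",
    "repulsion_direction",
    "simulate_trajectory",
    "generate_shell_game_trial",
    "shell_game_violation",
    "min_pairwise_distance",
    "mean_axis_step_length",
]

DYNAMICS_KINDS = ("constant_speed", "ou", "constrained_ou", "shell_game")

# Keeps reflected positions strictly inside [0, bound) so rasterization is safe.
_EDGE_EPS = 1e-9


class InvalidConfigError(ValueError):
    """Raised when an environment or trial configuration is inconsistent."""


class TrialGenerationError(RuntimeError):
    """Raised when a constrained trial generator exhausts its budget.

    ``binding_constraint`` names the constraint that caused the most
    rejections.
    """

    def __init__(self, message: str, binding_constraint: str):
        super().__init__(message)
        self.binding_constraint = binding_constraint


@dataclass(frozen=True)
class EnvironmentConfig:
    """Parameters of the moving-object environment.

    ``sigma`` is the speed parameter in pixels per update: the constant speed
    in the constant-speed regime, and the standard deviation of the velocity
    innovations in the OU regimes.  ``updates_per_second`` is the display
    update rate eta (Hz); a trial lasts ``n_updates / updates_per_second``
    seconds.  ``min_distance`` (pixels) is the repulsion radius in the
    constant-speed regime and a hard separation floor in the constrained-OU
    and shell-game regimes; 0 disables it.
    """

    dynamics_kind: str
    sigma: float
    arena: tuple[float, float]
    updates_per_second: float
    n_updates: int
    n_targets: int
    n_objects: int
    k: float = 0.0005
    lam: float = 0.9
    min_distance: float = 0.0

    def __post_init__(self):
        if self.dynamics_kind not in DYNAMICS_KINDS:
            raise InvalidConfigError(
                f"unknown dynamics_kind {self.dynamics_kind!r}; "
                f"expected one of {DYNAMICS_KINDS}"
            )
        if self.sigma < 0:
            raise InvalidConfigError("sigma must be non-negative")
        if not (0.0 <= self.lam <= 1.0):
            raise InvalidConfigError("lam must lie in [0, 1]")
        if self.k < 0:
            raise InvalidConfigError("k must be non-negative")
        if self.min_distance < 0:
            raise InvalidConfigError("min_distance must be non-negative")
        if self.n_targets > self.n_objects:
            raise InvalidConfigError("n_targets must not exceed n_objects")
        if self.n_targets < 0 or self.n_objects <= 0:
            raise InvalidConfigError("object counts must be positive")
        if self.n_updates < 1:
            raise InvalidConfigError("n_updates must be at least 1")
        if self.updates_per_second <= 0:
            raise InvalidConfigError("updates_per_second must be positive")
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise InvalidConfigError("arena dimensions must be positive")

    @property
    def duration_s(self) -> float:
        return self.n_updates / self.updates_per_second


@dataclass
class WorldState:
    """Instantaneous state of all objects.

    ``positions`` is an ``(n, 2)`` float array of (x, y) pixel coordinates.
    ``velocities`` is used by the OU regimes; ``headings`` (radians) and the
    config's ``sigma`` describe motion in the constant-speed regime.
    """

    time_index: int
    positions: np.ndarray
    velocities: np.ndarray
    headings: np.ndarray
    bounds: tuple[float, float]

    def copy(self) -> "WorldState":
        return WorldState(
            self.time_index,
            self.positions.copy(),
            self.velocities.copy(),
            self.headings.copy(),
            self.bounds,
        )


@dataclass
class Trajectory:
    """A serialized stimulus: per-frame object positions plus metadata.

    ``frames`` has shape ``(n_updates, n_objects, 2)``; frame 0 is the
    initial configuration.  ``target_mask`` holds the object indices that are
    targets; ``labels`` the per-target label strings (parallel to
    ``target_mask``).
    """

    frames: np.ndarray
    target_mask: np.ndarray
    config: EnvironmentConfig
    seed: Optional[int] = None
    labels: Optional[list[str]] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.target_mask = np.asarray(self.target_mask, dtype=int)
        if self.labels is None:
            self.labels = [str(i + 1) for i in range(len(self.target_mask))]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_objects(self) -> int:
        return self.frames.shape[1]

    @property
    def n_targets(self) -> int:
        return len(self.target_mask)


def _reflect(pos: np.ndarray, vel: np.ndarray, bounds: tuple[float, float]) -> None:
    """Reflect positions (and negate velocities) at the arena walls, in place."""
    for axis in range(2):
        hi = bounds[axis]
        p = pos[:, axis]
        # Repeated reflection handles the (rare) multi-wall overshoot.
        for _ in range(16):
            below = p < 0
            above = p >= hi
            if not (below.any() or above.any()):
                break
            p[below] = -p[below]
            vel[below, axis] = -vel[below, axis]
            p[above] = 2 * hi - p[above]
            vel[above, axis] = -vel[above, axis]
        np.clip(p, 0.0, hi - _EDGE_EPS, out=p)


def init_world(config: EnvironmentConfig, rng: np.random.Generator) -> WorldState:
    """Draw an initial configuration: uniform positions (respecting the
    minimum separation when one is required), zero velocities, and uniform
    random headings."""
    w, h = config.arena
    n = config.n_objects
    require_sep = config.min_distance > 0 and config.dynamics_kind in (
        "constrained_ou",
        "shell_game",
    )
    for _ in range(10_000):
        pos = rng.uniform(low=[0.0, 0.0], high=[w, h], size=(n, 2))
        if not require_sep or n < 2 or pdist(pos).min() >= config.min_distance:
            break
    else:
        raise InvalidConfigError(
            "could not place objects with the required minimum separation"
        )
    return WorldState(
        time_index=0,
        positions=pos,
        velocities=np.zeros((n, 2)),
        headings=rng.uniform(0.0, 2 * math.pi, size=n),
        bounds=(w, h),
    )


def _ou_velocity(state: WorldState, config: EnvironmentConfig,
                 rng: np.random.Generator) -> np.ndarray:
    center = np.array(config.arena) / 2.0
    w = rng.normal(0.0, config.sigma, size=state.positions.shape)
    return config.lam * state.velocities - config.k * (state.positions - center) + w


def ou_step(state: WorldState, config: EnvironmentConfig,
            rng: np.random.Generator) -> WorldState:
    """One update of the discrete OU recurrence.

    v_t = lam * v_{t-1} - k * (x_{t-1} - centre) + w_t,  w_t ~ N(0, sigma);
    x_t = x_{t-1} + v_t.  Positions are reflected at the arena walls (the
    velocity component normal to the wall is negated).
    """
    if config.sigma < 0:
        raise InvalidConfigError("sigma must be non-negative")
    vel = _ou_velocity(state, config, rng)
    pos = state.positions + vel
    _reflect(pos, vel, state.bounds)
    return WorldState(state.time_index + 1, pos, vel, state.headings.copy(),
                      state.bounds)


def constrained_ou_step(state: WorldState, config: EnvironmentConfig,
                        rng: np.random.Generator) -> WorldState:
    """OU update in which a position change is applied per object only if the
    resulting configuration keeps every pairwise distance at or above
    ``min_distance``.  Velocities are always updated.  Acceptance is
    evaluated sequentially in object-index order against the partially
    updated configuration, which makes the step deterministic given the
    innovations.
    """
    vel = _ou_velocity(state, config, rng)
    pos = state.positions.copy()
    n = pos.shape[0]
    md = config.min_distance
    for i in range(n):
        cand = pos[i] + vel[i]
        cand_arr = cand[None, :].copy()
        v_arr = vel[i][None, :].copy()
        _reflect(cand_arr, v_arr, state.bounds)
        cand = cand_arr[0]
        if md > 0 and n > 1:
            others = np.delete(pos, i, axis=0)
            if np.min(np.hypot(*(others - cand).T)) < md:
                continue  # hold position; velocity already updated
        pos[i] = cand
        vel[i] = v_arr[0]
    return WorldState(state.time_index + 1, pos, vel, state.headings.copy(),
                      state.bounds)


def repulsion_direction(state: WorldState, object_index: int,
                        min_distance: float) -> Optional[float]:
    """Net repulsion heading for one object.

    Sums, component-wise, the inverse-square-distance contributions of every
    other object and every wall lying within ``min_distance`` (perpendicular
    distance for walls), and returns the heading ``atan2(r_y, r_x)``.
    Returns ``None`` when the net vector is exactly zero (perfectly balanced
    configuration) or when nothing is within range; the caller keeps the
    current heading in either case.
    """
    pos = state.positions
    x, y = pos[object_index]
    rx = ry = 0.0
    found = False
    for j in range(pos.shape[0]):
        if j == object_index:
            continue
        dx = x - pos[j, 0]
        dy = y - pos[j, 1]
        d2 = dx * dx + dy * dy
        if 0 < d2 <= min_distance * min_distance:
            rx += dx / d2
            ry += dy / d2
            found = True
    w, h = state.bounds
    # Walls contribute along their inward normal: (x - wall)/(x - wall)^2.
    for d, sign, axis in ((x, 1.0, 0), (w - x, -1.0, 0),
                          (y, 1.0, 1), (h - y, -1.0, 1)):
        if 0 < d <= min_distance:
            if axis == 0:
                rx += sign / d
            else:
                ry += sign / d
            found = True
    if not found or (rx == 0.0 and ry == 0.0):
        return None
    return math.atan2(ry, rx)


def constant_speed_step(state: WorldState, config: EnvironmentConfig,
                        rng: np.random.Generator) -> WorldState:
    """Advance every object by ``sigma`` pixels along its heading, after
    re-aiming any object that has a neighbour or wall within
    ``min_distance`` toward its net repulsion direction."""
    pos = state.positions
    n = pos.shape[0]
    headings = state.headings.copy()
    md = config.min_distance
    if md > 0:
        for i in range(n):
            theta = repulsion_direction(state, i, md)
            if theta is not None:
                headings[i] = theta
    step = np.column_stack([np.cos(headings), np.sin(headings)]) * config.sigma
    new_pos = pos + step
    # Reflect headings at walls if the repulsion did not turn the object in time.
    vel = step.copy()
    _reflect(new_pos, vel, state.bounds)
    headings = np.arctan2(vel[:, 1], vel[:, 0])
    return WorldState(state.time_index + 1, new_pos,
                      state.velocities.copy(), headings, state.bounds)


_STEPPERS = {
    "ou": ou_step,
    "constrained_ou": constrained_ou_step,
    "constant_speed": constant_speed_step,
}


def simulate_trajectory(config: EnvironmentConfig, seed: int,
                        init_state: Optional[WorldState] = None) -> Trajectory:
    """Simulate a full trial and return its Trajectory.

    Frame 0 is the initial configuration; ``n_updates - 1`` dynamics steps
    follow, so the frame count equals ``config.n_updates``.  The first
    ``n_targets`` object indices are designated targets (objects are
    statistically exchangeable).
    """
    if config.dynamics_kind == "shell_game":
        raise InvalidConfigError(
            "shell-game trials are produced by generate_shell_game_trial"
        )
    rng = np.random.default_rng(seed)
    state = init_state.copy() if init_state is not None else init_world(config, rng)
    if (config.dynamics_kind == "constrained_ou" and config.min_distance > 0
            and config.n_objects > 1
            and pdist(state.positions).min() < config.min_distance):
        raise InvalidConfigError(
            "initial configuration violates the minimum object distance"
        )
    step = _STEPPERS[config.dynamics_kind]
    frames = np.empty((config.n_updates, config.n_objects, 2))
    frames[0] = state.positions
    for t in range(1, config.n_updates):
        state = step(state, config, rng)
        frames[t] = state.positions
    return Trajectory(frames=frames,
                      target_mask=np.arange(config.n_targets),
                      config=config, seed=seed)


def min_pairwise_distance(traj: Trajectory) -> float:
    """Minimum over all frames and object pairs of the Euclidean distance."""
    if traj.n_objects < 2:
        raise ValueError("min_pairwise_distance requires at least 2 objects")
    return min(pdist(frame).min() for frame in traj.frames)


# ---------------------------------------------------------------------------
# Shell-game trials
# ---------------------------------------------------------------------------

def _shell_game_frames(config: EnvironmentConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Candidate shell-game trajectory.

    Objects occupy stations on a horizontal line spaced ``L`` apart with
    ``L >= min_distance + margin``.  Repeatedly, a random adjacent pair of
    stations swaps occupants: the two objects traverse a semicircular arc
    about the pair's midpoint (radius L/2, so their mutual distance stays L)
    at linear speed ``sigma`` pixels per update.  Geometry guarantees that
    no pair ever comes closer than L.
    """
    w, h = config.arena
    n = config.n_objects
    margin = 30.0
    L = config.min_distance + margin
    if (n - 1) * L > w * 0.9:
        raise InvalidConfigError("arena too narrow for the station layout")
    x0 = (w - (n - 1) * L) / 2.0
    stations = np.array([[x0 + i * L, h / 2.0] for i in range(n)])
    station_of = list(range(n))  # object index -> station index
    frames = np.empty((config.n_updates, n, 2))
    pos = stations[station_of].copy()
    frames[0] = pos
    t = 1
    dphi = config.sigma / (L / 2.0)  # angular speed along the arc
    n_arc = max(1, math.ceil(math.pi / dphi)) if dphi > 0 else None
    while t < config.n_updates:
        if n_arc is None or t + n_arc > config.n_updates:
            frames[t:] = pos  # hold for the remaining frames
            break
        s = int(rng.integers(0, n - 1))  # stations s and s+1 swap occupants
        direction = 1.0 if rng.random() < 0.5 else -1.0
        obj_a = station_of.index(s)
        obj_b = station_of.index(s + 1)
        mid = (stations[s] + stations[s + 1]) / 2.0
        r = L / 2.0
        for j in range(1, n_arc + 1):
            phi = direction * min(math.pi, j * dphi)
            ca, sa = math.cos(phi), math.sin(phi)
            offset = np.array([-r * ca, -r * sa])  # object A starts at -r on x
            pos[obj_a] = mid + offset
            pos[obj_b] = mid - offset
            frames[t] = pos
            t += 1
        # Snap exactly onto the exchanged stations.
        pos[obj_a] = stations[s + 1]
        pos[obj_b] = stations[s]
        frames[t - 1] = pos
        station_of[obj_a], station_of[obj_b] = s + 1, s
    return frames


def shell_game_violation(traj: Trajectory, screening_params,
                         screening_seed: int) -> Optional[str]:
    """Check the three shell-game acceptance constraints.

    Returns ``None`` for an acceptable trial, or the name of the violated
    constraint: ``"min_distance"`` (some pair came closer than the floor) or
    ``"screening_id_accuracy"`` (the screening tracker — the attention-map
    model with ``f_corr = 0`` — labelled the trial perfectly, so the trial
    cannot produce identity errors).
    """
    from .model import run_model_on_trajectory  # local import avoids a cycle

    if traj.config.min_distance > 0 and min_pairwise_distance(traj) < \
            traj.config.min_distance:
        return "min_distance"
    result = run_model_on_trajectory(traj, screening_params, seed=screening_seed)
    if result.id_accuracy >= 1.0:
        return "screening_id_accuracy"
    return None


def generate_shell_game_trial(config: EnvironmentConfig, screening_params,
                              rng: np.random.Generator,
                              budget: int = 1000) -> Trajectory:
    """Generate an accepted shell-game trial.

    Candidates are drawn until one satisfies all constraints or the budget
    is exhausted, in which case :class:`TrialGenerationError` names the
    constraint that caused the most rejections.
    """
    if config.dynamics_kind != "shell_game":
        raise InvalidConfigError("config.dynamics_kind must be 'shell_game'")
    if config.n_objects != config.n_targets + 1:
        raise InvalidConfigError(
            "shell-game trials use exactly one distractor "
            "(n_objects = n_targets + 1)"
        )
    rejections: dict[str, int] = {}
    for _ in range(budget):
        seed = int(rng.integers(0, 2**31 - 1))
        cand_rng = np.random.default_rng(seed)
        frames = _shell_game_frames(config, cand_rng)
        traj = Trajectory(frames=frames, target_mask=np.arange(config.n_targets),
                          config=config, seed=seed)
        why = shell_game_violation(traj, screening_params,
                                   screening_seed=int(rng.integers(0, 2**31 - 1)))
        if why is None:
            return traj
        rejections[why] = rejections.get(why, 0) + 1
    binding = max(rejections, key=rejections.get)
    raise TrialGenerationError(
        f"no acceptable shell-game trial in {budget} candidates "
        f"(rejections: {rejections})", binding_constraint=binding)


# ---------------------------------------------------------------------------
# Displacement statistic behind the OU speed conversion
# ---------------------------------------------------------------------------

def mean_axis_step_length(sigma: float, k: float = 0.0005, lam: float = 0.9,
                          n_updates: int = 100_000, n_runs: int = 100,
                          seed: int = 0) -> float:
    """Mean absolute per-axis displacement per update, in pixels, for the
    unconstrained OU recurrence started from zero velocity.

    This is the distance statistic behind the empirical-to-simulation speed
    conversion for OU displays: with ``k = 0.0005`` and ``lam = 0.9`` it
    converges to about ``1.8 * sigma``.  (The mean *Euclidean* step length
    is larger by construction — see the methods note.)  ``n_updates`` is the
    total number of per-object updates accumulated across ``n_runs``
    independent runs.
    """
    rng = np.random.default_rng(seed)
    per_run = max(1, math.ceil(n_updates / n_runs))
    total = 0.0
    count = 0
    for _ in range(n_runs):
        x = np.zeros(2)
        v = np.zeros(2)
        w = rng.normal(0.0, sigma, size=(per_run, 2))
        for t in range(per_run):
            v = lam * v - k * x + w[t]
            x = x + v
            total += abs(v[0]) + abs(v[1])
            count += 2
    return total / count
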