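"""The attention-map tracking model.

Tracking is maintained as a set of *attended locations* on a retinotopic
grid.  The environment provides, at every display frame, only a grid map of
instantaneous object locations (``ObjectMap``); the model has no access to
velocities or object identities.  At a total budget of ``f_loc`` updates per
second, one attended location at a time is revisited: if its cell still
holds an object it is confirmed in place, otherwise it moves to the nearest
occupied cell within a search bound ``nob`` (and is dropped if none is
found).

A single capacity-two *unitary* buffer augments the map: it locks onto the
attended location in the greatest danger of confusion (largest
first-to-second nearest-object distance ratio, exponent ``c_e``), stores its
last two updated locations, and when that location is next updated starts
the nearest-object search from the linearly extrapolated position instead
of the stale one.  The lock may switch threads at most every ``1/f_u``
seconds, and switching discards the stored locations.

Grid cells are addressed ``(row, col)`` with ``row = floor(y)`` and
``col = floor(x)`` at the default resolution of one cell per display pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .dynamics import Trajectory
from . import identity

__all__ = [
    "ModelParams",
    "ObjectMap",
    "AttentionMap",
    "UnitaryBuffer",
    "TickEvent",
    "TrialResult",
    "rasterize",
    "nearest_object_location",
    "kth_nearest_object_location",
    "confusion_ratio",
    "unitary_selection_probabilities",
    "select_unitary_lock",
    "unitary_extrapolate",
    "attention_tick",
    "RoundRobinState",
    "resolve_claims",
    "run_model_on_trajectory",
]

Cell = tuple[int, int]

SCHEDULERS = ("round_robin", "crowding_priority")


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the tracking model.

    f_loc : total attention-update frequency in Hz, shared across all
        attended locations.
    f_u : frequency (Hz) at which the unitary lock may reselect which
        attended location it processes (the literature suggests 3-10 Hz).
    c_e : confusion exponent; ``inf`` selects the most confusable location
        deterministically.
    nob : nearest-object search bound in cells (Euclidean); ``inf`` means
        the whole grid.
    f_corr : probability, per location update, that the identity sequence is
        re-synchronised with the new spatial order (0 = never, 1 = always).
    scheduler : order of location updates — ``round_robin`` (cyclic) or
        ``crowding_priority`` (sampled by confusion ratio).
    capacity : maximum number of attended locations.
    """

    f_loc: float
    f_u: float = 10.0
    c_e: float = math.inf
    nob: float = math.inf
    f_corr: float = 0.0
    scheduler: str = "round_robin"
    capacity: int = 8

    def __post_init__(self):
        if self.f_loc <= 0 or self.f_u <= 0:
            raise ValueError("f_loc and f_u must be positive")
        if not (0.0 <= self.f_corr <= 1.0):
            raise ValueError("f_corr must lie in [0, 1]")
        if self.c_e < 0:
            raise ValueError("c_e must be non-negative")
        if self.nob < 0:
            raise ValueError("nob must be non-negative")
        if self.scheduler not in SCHEDULERS:
            raise ValueError(f"scheduler must be one of {SCHEDULERS}")


class ObjectMap:
    """Grid of instantaneous object counts.

    Stored sparsely as a mapping ``(row, col) -> count``; the dense ``grid``
    array is materialised on demand.  The sum of all cells equals the number
    of rasterized objects.
    """

    def __init__(self, cells: dict[Cell, int], grid_size: tuple[int, int]):
        self.cells = cells
        self.grid_size = grid_size
        self.n_objects = sum(cells.values())

    @property
    def grid(self) -> np.ndarray:
        g = np.zeros(self.grid_size, dtype=int)
        for (r, c), n in self.cells.items():
            g[r, c] = n
        return g

    def count_at(self, cell: Cell) -> int:
        return self.cells.get(cell, 0)


def rasterize(positions: np.ndarray, grid_size: tuple[int, int]) -> ObjectMap:
    """Bin continuous (x, y) positions onto the grid (floor convention).

    Each object increments exactly one cell; a position outside the grid is
    an error.
    """
    rows, cols = grid_size
    cells: dict[Cell, int] = {}
    for x, y in np.asarray(positions, dtype=float):
        r, c = int(math.floor(y)), int(math.floor(x))
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"position ({x}, {y}) lies outside the grid")
        cells[(r, c)] = cells.get((r, c), 0) + 1
    return ObjectMap(cells, grid_size)


def _search_key(cell: Cell, origin: Cell) -> tuple:
    """Ordering that replicates an expanding-square-ring scan.

    Rings are scanned outward in Chebyshev shells; within a shell the
    smallest Euclidean distance wins, and exact Euclidean ties resolve to
    the earliest cell in row-major scan order.  Globally that is the
    lexicographic order (d^2, Chebyshev shell, row, col).
    """
    dr = cell[0] - origin[0]
    dc = cell[1] - origin[1]
    return (dr * dr + dc * dc, max(abs(dr), abs(dc)), cell[0], cell[1])


def nearest_object_location(o: ObjectMap, origin: Cell,
                            nob: float = math.inf) -> Optional[Cell]:
    """Occupied cell of minimum Euclidean distance from ``origin`` within
    radius ``nob``, or ``None`` when no object lies within the bound."""
    nob2 = nob * nob
    best = None
    best_key = None
    for cell in o.cells:
        key = _search_key(cell, origin)
        if key[0] <= nob2 and (best_key is None or key < best_key):
            best, best_key = cell, key
    return best


def kth_nearest_object_location(o: ObjectMap, origin: Cell,
                                k: int) -> Optional[Cell]:
    """The k-th occupied cell by distance from ``origin`` (k >= 1), with
    multiplicity: a cell holding two objects occupies two consecutive ranks.
    Returns ``None`` when fewer than k objects exist."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if o.n_objects < k:
        return None
    ordered = sorted(o.cells, key=lambda cell: _search_key(cell, origin))
    cum = 0
    for cell in ordered:
        cum += o.cells[cell]
        if cum >= k:
            return cell
    return None


def _distance(a: Cell, b: Cell) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def confusion_ratio(o: ObjectMap, a_i: Cell, c_e: float) -> float:
    """Confusion ratio of an attended location:
    ``(d1 / d2) ** c_e`` where d1, d2 are the distances to the first- and
    second-nearest objects.  Zero first distance means the target is
    unambiguous (ratio 0 by convention); equal distances give 1 for any
    exponent.  Requires at least two objects on the map."""
    if o.n_objects < 2:
        raise ValueError("confusion ratio requires at least 2 objects")
    first = kth_nearest_object_location(o, a_i, 1)
    second = kth_nearest_object_location(o, a_i, 2)
    d1 = _distance(a_i, first)
    d2 = _distance(a_i, second)
    if d1 == 0.0:
        return 0.0
    ratio = d1 / d2
    if math.isinf(c_e):
        return 1.0 if ratio == 1.0 else 0.0
    return ratio ** c_e


def unitary_selection_probabilities(ratios) -> np.ndarray:
    """Normalise confusion ratios into selection probabilities
    (p_i = c_i / sum_j c_j); an all-zero input falls back to the uniform
    distribution."""
    r = np.asarray(ratios, dtype=float)
    if np.any(r < 0):
        raise ValueError("confusion ratios must be non-negative")
    total = r.sum()
    if total == 0.0:
        return np.full(r.shape, 1.0 / r.size)
    return r / total


@dataclass
class UnitaryBuffer:
    """Capacity-two location store of the unitary thread.

    ``u`` is the most recent location of the locked thread, ``v`` the one
    before; both belong to the thread ``locked_tid``, and switching locks
    empties them.  ``lock_time`` is the simulated time (s) of the last lock
    decision.
    """

    u: Optional[Cell] = None
    v: Optional[Cell] = None
    locked_tid: Optional[int] = None
    lock_time: Optional[float] = None

    @property
    def full(self) -> bool:
        return self.u is not None and self.v is not None

    def push(self, cell: Cell) -> None:
        self.v = self.u
        self.u = cell


class AttentionMap:
    """Attended locations, keyed by a stable thread id.

    Thread ids are assigned at initialisation and never reused; locations
    may be dropped, never added mid-trial.  The dense count grid is
    materialised on demand.
    """

    def __init__(self, cells: list[Cell], grid_size: tuple[int, int]):
        self.grid_size = grid_size
        self._cells: dict[int, Cell] = {tid: cell for tid, cell in enumerate(cells)}
        self.order: list[int] = list(self._cells)  # stable scheduling order
        self.initial_capacity = len(cells)

    @property
    def attended_list(self) -> list[Cell]:
        return [self._cells[tid] for tid in self.order]

    @property
    def live_tids(self) -> list[int]:
        return list(self.order)

    @property
    def grid(self) -> np.ndarray:
        g = np.zeros(self.grid_size, dtype=int)
        for cell in self._cells.values():
            g[cell] += 1
        return g

    def __len__(self) -> int:
        return len(self.order)

    def cell(self, tid: int) -> Cell:
        return self._cells[tid]

    def move(self, tid: int, cell: Cell) -> None:
        self._cells[tid] = cell

    def drop(self, tid: int) -> None:
        del self._cells[tid]
        self.order.remove(tid)


def unitary_extrapolate(u: UnitaryBuffer, a_i: Cell,
                        grid_size: tuple[int, int]) -> Cell:
    """Velocity-extrapolated search origin ``a_i + (u - v)``, clipped to the
    grid.  Requires both buffer entries."""
    if not u.full:
        raise ValueError("unitary buffer does not hold two locations")
    r = a_i[0] + u.u[0] - u.v[0]
    c = a_i[1] + u.u[1] - u.v[1]
    return (min(max(r, 0), grid_size[0] - 1), min(max(c, 0), grid_size[1] - 1))


def _thread_ratios(a: AttentionMap, o: ObjectMap, c_e: float) -> np.ndarray:
    if o.n_objects < 2:
        return np.ones(len(a))
    return np.array([confusion_ratio(o, a.cell(tid), c_e) for tid in a.order])


def _select_by_confusion(a: AttentionMap, o: ObjectMap, c_e: float,
                         rng: np.random.Generator) -> int:
    """Choose a thread id per the confusion-ratio rule.  An infinite
    exponent is implemented as a deterministic argmax of the base ratio with
    lowest-index tie-break (avoiding overflow)."""
    if math.isinf(c_e):
        base = _thread_ratios(a, o, 1.0)
        return a.order[int(np.argmax(base))]
    p = unitary_selection_probabilities(_thread_ratios(a, o, c_e))
    return a.order[int(rng.choice(len(p), p=p))]


def select_unitary_lock(a: AttentionMap, o: ObjectMap, u: UnitaryBuffer,
                        params: ModelParams, now: float,
                        rng: np.random.Generator) -> UnitaryBuffer:
    """Re-evaluate the unitary lock at time ``now`` (seconds).

    The lock is refractory: within ``1/f_u`` seconds of the last decision
    the buffer is returned unchanged.  Otherwise a thread is drawn per the
    confusion-ratio rule; a lock switch empties the stored locations, while
    re-selecting the incumbent retains them.  An empty attended list clears
    the buffer.
    """
    if len(a) == 0:
        return UnitaryBuffer(lock_time=u.lock_time)
    if u.lock_time is not None and (now - u.lock_time) < 1.0 / params.f_u:
        return u
    tid = _select_by_confusion(a, o, params.c_e, rng)
    if tid == u.locked_tid:
        return replace(u, lock_time=now)
    return UnitaryBuffer(locked_tid=tid, lock_time=now)


@dataclass
class TickEvent:
    tid: int
    kind: str  # "confirmed" | "moved" | "dropped"
    old_cell: Cell
    new_cell: Optional[Cell]


class RoundRobinState:
    """Cyclic pointer over live thread ids (skips dropped threads)."""

    def __init__(self):
        self._next = 0

    def pick(self, a: AttentionMap) -> int:
        tid = a.order[self._next % len(a.order)]
        self._next = (self._next % len(a.order)) + 1
        return tid


def attention_tick(a: AttentionMap, o_now: ObjectMap, u: UnitaryBuffer,
                   params: ModelParams, scheduler_state: RoundRobinState,
                   rng: np.random.Generator) -> TickEvent:
    """Spend one attention update on a single attended location.

    The location is chosen by the configured scheduler.  If its cell is
    still occupied it is confirmed in place; otherwise the nearest-object
    search runs from the velocity-extrapolated origin (when the location is
    the unitary lock with a full buffer) or from the stale location itself,
    bounded by ``nob``.  A failed search drops the location.  Updates of the
    locked thread push its new location into the unitary buffer.
    """
    if len(a) == 0:
        raise ValueError("attention_tick requires a non-empty attended list")
    if params.scheduler == "round_robin":
        tid = scheduler_state.pick(a)
    else:
        tid = _select_by_confusion(a, o_now, params.c_e, rng)
    cell = a.cell(tid)
    locked = tid == u.locked_tid
    if o_now.count_at(cell) > 0:
        # Confirmed in place: the buffer is not pushed (a push only happens
        # when the location actually changes), so the stored pair keeps
        # spanning one genuine displacement of the locked thread.
        return TickEvent(tid, "confirmed", cell, cell)
    origin = cell
    if locked and u.full:
        origin = unitary_extrapolate(u, cell, a.grid_size)
    found = nearest_object_location(o_now, origin, params.nob)
    if found is None:
        a.drop(tid)
        if locked:
            u.u = u.v = None
            u.locked_tid = None
        return TickEvent(tid, "dropped", cell, None)
    a.move(tid, found)
    if locked:
        u.push(found)
    return TickEvent(tid, "moved", cell, found)


@dataclass
class TrialResult:
    """Outcome of running the model on one trial.

    ``k`` of the ``n`` targets were claimed by surviving attended locations
    (tracking accuracy k/n); ``p`` reported objects carried their correct
    start-of-trial label (identity accuracy p/n).
    """

    n: int
    k: int
    p: int
    tracking_accuracy: float
    id_accuracy: float
    n_dropped: int
    seed: Optional[int]
    params: ModelParams
    claims: list[tuple[int, int]] = field(default_factory=list)  # (tid, object)
    assignment: list[tuple[int, str]] = field(default_factory=list)  # (object, label)

    def __post_init__(self):
        assert 0 <= self.p <= self.k <= self.n


def resolve_claims(thread_cells: dict[int, Cell],
                   object_cells: list[Cell]) -> list[tuple[int, int]]:
    """End-of-trial response protocol.

    Each surviving attended location claims one object; claims are resolved
    greedily by ascending location-to-object distance with every object
    claimable at most once.  Returns (thread id, object index) pairs.
    Dropped locations yield no claim.
    """
    pairs = sorted(
        (( _distance(cell, object_cells[j]), tid, j)
         for tid, cell in thread_cells.items()
         for j in range(len(object_cells))),
    )
    claimed_threads: set[int] = set()
    claimed_objects: set[int] = set()
    claims = []
    for _, tid, j in pairs:
        if tid in claimed_threads or j in claimed_objects:
            continue
        claims.append((tid, j))
        claimed_threads.add(tid)
        claimed_objects.add(j)
        if len(claimed_threads) == len(thread_cells):
            break
    return claims


def run_model_on_trajectory(traj: Trajectory, params: ModelParams,
                            seed: Optional[int] = None,
                            grid_size: Optional[tuple[int, int]] = None,
                            record_events: bool = False) -> TrialResult:
    """Run the tracker over a full trial and score it.

    Attended locations are initialised on the targets' frame-0 cells.  The
    environment advances at ``eta = config.updates_per_second`` Hz while
    attention ticks are dispensed at ``f_loc`` Hz through a fractional-tick
    accumulator (both ``f_loc > eta`` and ``f_loc < eta`` work), and the
    unitary lock is re-evaluated before every tick at its own ``f_u``-gated
    cadence.  At the final frame the response protocol produces the claimed
    objects, tracking accuracy ``k/n`` and identity accuracy ``p/n``.

    The identity sequence is maintained throughout at correspondence
    probability ``params.f_corr``.
    """
    config = traj.config
    n = traj.n_targets
    if params.capacity < n:
        raise ValueError(
            f"capacity {params.capacity} is below the target count {n}")
    if grid_size is None:
        grid_size = (int(math.ceil(config.arena[1])),
                     int(math.ceil(config.arena[0])))
    rng = np.random.default_rng(seed)
    eta = config.updates_per_second

    o0 = rasterize(traj.frames[0], grid_size)
    target_cells = [
        (int(math.floor(traj.frames[0][j, 1])), int(math.floor(traj.frames[0][j, 0])))
        for j in traj.target_mask
    ]
    a = AttentionMap(target_cells, grid_size)
    tid_to_object = {tid: int(obj) for tid, obj in enumerate(traj.target_mask)}
    labels = list(traj.labels)
    ids = identity.init_id_sequence(
        [(tid, target_cells[tid]) for tid in range(n)], labels, params.f_corr)

    u = UnitaryBuffer()
    sched = RoundRobinState()
    acc = 0.0
    events: list[TickEvent] = []
    o_now = o0
    for f in range(traj.n_frames):
        acc += params.f_loc / eta
        m = int(math.floor(acc))
        if m == 0:
            continue
        acc -= m
        if f > 0:
            o_now = rasterize(traj.frames[f], grid_size)
        for j in range(m):
            if len(a) == 0:
                break
            now = (f + (j + 0.5) / m) / eta
            u = select_unitary_lock(a, o_now, u, params, now, rng)
            ev = attention_tick(a, o_now, u, params, sched, rng)
            if record_events:
                events.append(ev)
            if ev.kind == "moved":
                identity.correspondence_update(
                    ids, ev.tid, ev.new_cell,
                    {tid: a.cell(tid) for tid in a.live_tids}, rng)
            elif ev.kind == "dropped":
                identity.remove_thread(ids, ev.tid)

    final = traj.frames[-1]
    object_cells = [
        (int(math.floor(final[j, 1])), int(math.floor(final[j, 0])))
        for j in range(traj.n_objects)
    ]
    thread_cells = {tid: a.cell(tid) for tid in a.live_tids}
    claims = resolve_claims(thread_cells, object_cells)
    target_set = set(int(j) for j in traj.target_mask)
    k = sum(1 for _, obj in claims if obj in target_set)

    assignment = identity.final_id_assignment(
        ids, thread_cells, {tid: obj for tid, obj in claims})
    truth = {tid_to_object[tid]: labels[tid] for tid in range(n)}
    p = identity.correct_label_count(assignment, truth)

    result = TrialResult(
        n=n, k=k, p=p,
        tracking_accuracy=k / n,
        id_accuracy=p / n,
        n_dropped=n - len(a),
        seed=seed,
        params=params,
        claims=claims,
        assignment=assignment,
    )
    if record_events:
        result.events = events  # type: ignore[attr-defined]
        result.debug = {  # type: ignore[attr-defined]
            "thread_cells": thread_cells, "object_cells": object_cells,
            "tid_to_object": tid_to_object, "target_set": target_set,
            "labels": labels, "ids": ids,
        }
    return result
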