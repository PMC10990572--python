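"""Identity maintenance without indexes.

Target labels are not bound to objects through pointers.  Instead the system
keeps a single ordered sequence of labels, aligned with the spatial sort
order of the attended locations (ascending x, ties broken by ascending y).
At trial start the sequence simply lists the labels of the targets in sorted
order.  Whenever an attended location is relocated, with probability
``f_corr`` a *correspondence update* re-inserts that location's label at its
new sorted rank; with probability ``1 - f_corr`` the sequence goes stale.
At trial end the labels are read off against the reported objects in sorted
order, so identity errors arise exactly when the spatial order changed
without the sequence keeping up.

Locations are grid cells ``(row, col)``; note the sort key is ``(x, y)`` =
``(col, row)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IDState",
    "sorted_order",
    "init_id_sequence",
    "correspondence_update",
    "remove_thread",
    "final_id_assignment",
    "id_accuracy",
    "correct_label_count",
]

Cell = tuple[int, int]


def _sort_key(cell: Cell) -> tuple[int, int]:
    # x ascending, then y ascending
    return (cell[1], cell[0])


def sorted_order(locations: Sequence[Cell]) -> list[int]:
    """Stable permutation sorting locations by x, ties by y, remaining ties
    by input index.  Returns the list of input indices in sorted order."""
    return sorted(range(len(locations)), key=lambda i: (_sort_key(locations[i]), i))


@dataclass
class IDState:
    """The maintained label sequence and the rank each thread's label holds.

    Invariant: ``id_sequence[rank_of_thread[tid]]`` is the label bound to
    thread ``tid``; ranks form a permutation of ``0..len-1``.
    """

    id_sequence: list[str]
    rank_of_thread: dict[int, int]
    f_corr: float

    def label_of(self, tid: int) -> str:
        return self.id_sequence[self.rank_of_thread[tid]]


def init_id_sequence(threads: Sequence[tuple[int, Cell]], labels: Sequence[str],
                     f_corr: float) -> IDState:
    """Initial sequence: labels listed in the sorted order of their threads'
    starting locations.  ``threads`` pairs a stable thread id with its
    initial cell; ``labels[i]`` belongs to ``threads[i]``."""
    if len(threads) != len(labels):
        raise ValueError("need exactly one label per thread")
    if not (0.0 <= f_corr <= 1.0):
        raise ValueError("f_corr must lie in [0, 1]")
    order = sorted(range(len(threads)),
                   key=lambda i: (_sort_key(threads[i][1]), threads[i][0]))
    id_sequence = [labels[i] for i in order]
    rank_of_thread = {threads[i][0]: rank for rank, i in enumerate(order)}
    return IDState(id_sequence=id_sequence, rank_of_thread=rank_of_thread,
                   f_corr=f_corr)


def correspondence_update(state: IDState, thread_index: int, new_location: Cell,
                          all_locations: dict[int, Cell],
                          rng: np.random.Generator) -> IDState:
    """Stochastic re-synchronisation after a location update.

    With probability ``f_corr`` the moved thread's label is removed from the
    sequence and re-inserted at the thread's new sorted rank among the
    current attended locations (other labels keep their relative order);
    with probability ``1 - f_corr`` the sequence is left stale.  Must be
    called exactly once per attention tick that relocated a thread.
    """
    if thread_index not in state.rank_of_thread:
        raise KeyError(f"unknown thread {thread_index}")
    if state.f_corr <= 0.0:
        return state
    if state.f_corr < 1.0 and rng.random() >= state.f_corr:
        return state
    old_rank = state.rank_of_thread[thread_index]
    label = state.id_sequence.pop(old_rank)
    for tid, r in state.rank_of_thread.items():
        if r > old_rank:
            state.rank_of_thread[tid] = r - 1
    new_rank = sum(
        1 for tid, cell in all_locations.items()
        if tid != thread_index
        and (_sort_key(cell), tid) < (_sort_key(new_location), thread_index)
    )
    state.id_sequence.insert(new_rank, label)
    for tid, r in state.rank_of_thread.items():
        if r >= new_rank:
            state.rank_of_thread[tid] = r + 1
    state.rank_of_thread[thread_index] = new_rank
    return state


def remove_thread(state: IDState, thread_index: int) -> IDState:
    """Drop a thread's label from the sequence (the label is lost and any
    report that needed it scores as incorrect)."""
    rank = state.rank_of_thread.pop(thread_index)
    state.id_sequence.pop(rank)
    for tid, r in state.rank_of_thread.items():
        if r > rank:
            state.rank_of_thread[tid] = r - 1
    return state


def final_id_assignment(state: IDState, final_locations: dict[int, Cell],
                        reported_objects: dict[int, int]
                        ) -> list[tuple[int, str]]:
    """Attach the maintained labels to the reported objects.

    The surviving attended locations are sorted once more by the same rule
    used throughout (x ascending, then y), and the k-th label in the
    sequence attaches to the object reported at or nearest the k-th
    location.  ``final_locations`` maps thread id to its final cell;
    ``reported_objects`` maps thread id to the object index it claimed.
    Returns (object index, label) pairs.
    """
    if len(final_locations) != len(state.id_sequence):
        raise ValueError("one surviving location per surviving label expected")
    order = sorted(final_locations,
                   key=lambda tid: (_sort_key(final_locations[tid]), tid))
    return [(reported_objects[tid], state.id_sequence[rank])
            for rank, tid in enumerate(order) if tid in reported_objects]


def correct_label_count(assignment: Sequence[tuple[int, str]],
                        ground_truth_labels: dict[int, str]) -> int:
    """Number of reported objects that are the true bearer of their assigned
    label (a distractor bears no label, so any label on it is incorrect)."""
    return sum(1 for obj, label in assignment
               if ground_truth_labels.get(obj) == label)


def id_accuracy(assignment: Sequence[tuple[int, str]],
                ground_truth_labels: dict[int, str]) -> float:
    """p / n: the fraction of the n true labels that ended up on their
    bearer."""
    n = len(ground_truth_labels)
    if n < 1:
        raise ValueError("at least one target required")
    return correct_label_count(assignment, ground_truth_labels) / n
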