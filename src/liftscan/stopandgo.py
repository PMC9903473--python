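"""Stop-and-go baseline scheduler and the method comparison study.

The baseline visits every cell individually: the stage moves to the cell,
halts, waits out a pause for the medium to settle, and transfers.  Wells
are worked through one after another, cells within a well in ascending x.
Total time is the sum of the point-to-point move times plus one pause per
stop.  ``compare_methods`` reproduces the simulation study contrasting
this baseline with the continuous scan over seeded random distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinematics import StageKinematics, move_time_1d
from .plate import CellTarget, PlateLayout, sample_cells
from .planner import build_line_grid, continuous_total_time

__all__ = [
    "StopGoSchedule",
    "CompareRow",
    "order_stop_and_go",
    "schedule_stop_and_go",
    "compare_methods",
    "compare_table",
]

MOVE_MODELS = ("max", "euclidean", "sequential")


@dataclass
class StopGoSchedule:
    """A timed stop-and-go visit sequence."""

    visit_order: list[int]
    move_times: np.ndarray
    pause: float
    total_time: float


@dataclass(frozen=True)
class CompareRow:
    """One row of the method-comparison table."""

    n_cells: int
    pause_s: float
    stopgo_mean_s: float
    continuous_mean_s: float
    ratio: float


def order_stop_and_go(
    targets: Sequence[CellTarget], layout: PlateLayout | None = None
) -> list[CellTarget]:
    """Visit order of the baseline: well after well, ascending x.

    Wells are processed in ascending well index (row-major over the
    grid); within a well targets sort by ascending x, ties broken by
    ascending y.  ``layout`` is accepted for interface symmetry but the
    ordering needs only the targets' well indices.
    """
    return sorted(targets, key=lambda t: (t.well_index, t.x, t.y))


def _pairwise_move_times(
    dx: np.ndarray, dy: np.ndarray, kin: StageKinematics, move_model: str
) -> np.ndarray:
    if move_model == "max":
        return np.maximum(move_time_1d(np.abs(dx), kin), move_time_1d(np.abs(dy), kin))
    if move_model == "euclidean":
        return np.atleast_1d(move_time_1d(np.hypot(dx, dy), kin))
    if move_model == "sequential":
        return move_time_1d(np.abs(dx), kin) + move_time_1d(np.abs(dy), kin)
    raise ValueError(f"unknown move_model {move_model!r}; choose from {MOVE_MODELS}")


def schedule_stop_and_go(
    ordered_targets: Sequence[CellTarget],
    kin: StageKinematics,
    pause: float = 1.0,
    move_model: str = "max",
) -> StopGoSchedule:
    """Total up the baseline: one pause per cell plus the moves between.

    The stage starts at the first target (no approach move), so a single
    target costs exactly one pause.  ``move_model`` selects how the 2-D
    point-to-point move time is formed from the per-axis profiles:
    ``"max"`` (simultaneous axes, default), ``"euclidean"`` (single
    profile along the straight-line distance) or ``"sequential"``
    (axes moved one after the other).
    """
    if move_model not in MOVE_MODELS:
        raise ValueError(f"unknown move_model {move_model!r}; choose from {MOVE_MODELS}")
    n = len(ordered_targets)
    if n == 0:
        return StopGoSchedule([], np.zeros(0), pause, 0.0)
    xs = np.array([t.x for t in ordered_targets], dtype=float)
    ys = np.array([t.y for t in ordered_targets], dtype=float)
    moves = _pairwise_move_times(np.diff(xs), np.diff(ys), kin, move_model)
    total = float(np.sum(moves)) + n * pause
    return StopGoSchedule(
        visit_order=[t.id for t in ordered_targets],
        move_times=np.asarray(moves, dtype=float),
        pause=pause,
        total_time=total,
    )


def compare_methods(
    n_cells: int,
    pause: float,
    reps: int,
    base_seed: int,
    kin: StageKinematics,
    layout: PlateLayout,
    pitch: float = 0.050,
    tolerance: float = 0.025,
    t_switch: float = 0.04,
    move_model: str = "max",
    line_length: float | None = None,
) -> CompareRow:
    """Stop-and-go vs continuous over ``reps`` seeded distributions.

    Each replicate draws a fresh distribution with seed
    ``base_seed + r`` and schedules it with both methods; the row carries
    the two mean times and their ratio (mean stop-and-go over mean
    continuous, matching how the study tabulates it).  The same pause is
    applied per stop (baseline) and per line end (continuous).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    grid = build_line_grid(layout, pitch, tolerance, travel_length=line_length)
    sg_times = np.empty(reps)
    ct_times = np.empty(reps)
    for r in range(reps):
        targets = sample_cells(n_cells, layout, base_seed + r)
        ordered = order_stop_and_go(targets, layout)
        sg_times[r] = schedule_stop_and_go(
            ordered, kin, pause=pause, move_model=move_model
        ).total_time
        ct_times[r] = continuous_total_time(
            targets, grid, kin, t_switch=t_switch, pause=pause
        )
    sg_mean = float(sg_times.mean())
    ct_mean = float(ct_times.mean())
    ratio = sg_mean / ct_mean if ct_mean > 0 else float("inf")
    return CompareRow(n_cells, pause, sg_mean, ct_mean, ratio)


def compare_table(
    n_cells_list: Sequence[int],
    pauses: Sequence[float],
    reps: int,
    base_seed: int,
    kin: StageKinematics,
    layout: PlateLayout,
    **kwargs,
):
    """Full comparison report: one row per (n_cells, pause) combination.

    Returns a pandas DataFrame with columns n_cells, pause_s,
    stopgo_mean_s, continuous_mean_s, ratio.
    """
    import pandas as pd

    rows = [
        compare_methods(n, p, reps, base_seed, kin, layout, **kwargs)
        for n in n_cells_list
        for p in pauses
    ]
    return pd.DataFrame([r.__dict__ for r in rows])
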