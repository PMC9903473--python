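"""Continuous-scan trigger planning: the time-effective transfer path.

Instead of stopping at every cell, the stage sweeps straight lines spaced
50 um apart along the plate's long axis and fires the laser on the fly
whenever a target lies within the 25 um transfer tolerance of the current
line.  Lines that come near no target are skipped entirely.  With an
80 mm usable band this yields N = 1600 candidate lines; total time is

    t_total = V * (t_line + pause) + (V - 1) * t_switch

over the V visited lines, where ``t_line`` follows the trapezoidal/
triangular move-time closed form, ``t_switch`` is the fixed line-step
time (0.04 s on the demonstrator) and ``pause`` lets the medium settle
after each line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .kinematics import StageKinematics, move_time_1d, time_at_distance
from .plate import CellTarget, PlateLayout

__all__ = [
    "LineGrid",
    "TriggerEvent",
    "LinePlan",
    "ContinuousSchedule",
    "GridConfigError",
    "TargetOutOfBandError",
    "build_line_grid",
    "assign_targets",
    "plan_serpentine",
    "trigger_time",
    "schedule_continuous",
    "continuous_total_time",
    "throughput_time",
    "min_separation_violations",
    "write_schedule_csv",
]


class GridConfigError(ValueError):
    """Raised for line-grid configurations that leave uncovered bands."""


class TargetOutOfBandError(ValueError):
    """Raised when a target lies outside the scanned band."""


@dataclass(frozen=True)
class LineGrid:
    """The raster of candidate scan lines over the usable area.

    ``line_ys`` are the y positions (mm) of the N lines; every line runs
    the full ``travel_length`` in x starting at ``x_start``.
    """

    pitch: float
    tolerance: float
    line_ys: np.ndarray
    travel_length: float
    x_start: float

    @property
    def n(self) -> int:
        return len(self.line_ys)

    @property
    def x_end(self) -> float:
        return self.x_start + self.travel_length


@dataclass
class TriggerEvent:
    """One laser firing: position on the line, timing, and the target(s).

    Targets sharing the exact same x on one line merge into a single
    event carrying all their ids.  ``t_offset`` is seconds from the start
    of the line traversal (filled in by :func:`schedule_continuous`);
    ``lateral_error`` is the across-track distance target-to-line (mm).
    """

    target_ids: tuple[int, ...]
    x: float
    y_line: float
    lateral_error: float
    t_offset: float = float("nan")
    t_absolute: float = float("nan")


@dataclass
class LinePlan:
    """One visited scan line: index in the grid, y, direction, triggers."""

    line_index: int
    y: float
    direction: int = +1  # +1 -> +x traversal, -1 -> -x
    triggers: list[TriggerEvent] = field(default_factory=list)


@dataclass
class ContinuousSchedule:
    """A fully timed continuous-scan plan."""

    visited_lines: int
    t_line: float
    t_switch: float
    pause: float
    total_time: float
    plans: list[LinePlan]
    line_start_times: list[float]


def build_line_grid(
    layout: PlateLayout,
    pitch: float = 0.050,
    tolerance: float = 0.025,
    travel_length: float | None = None,
) -> LineGrid:
    """Lay out N = floor(L_y / pitch) scan lines across the usable band.

    The first line sits ``pitch/2`` above the band edge so the tolerance
    discs tile the band exactly when ``tolerance == pitch/2``.

    Raises
    ------
    GridConfigError
        If ``tolerance > pitch/2`` (the configuration the grid math does
        not support) or ``pitch`` exceeds the band height.
    """
    if pitch <= 0:
        raise GridConfigError("pitch must be positive")
    if tolerance <= 0:
        raise GridConfigError("tolerance must be positive")
    if tolerance > pitch / 2.0 + 1e-12:
        raise GridConfigError(
            f"tolerance {tolerance} mm exceeds pitch/2 = {pitch / 2.0} mm"
        )
    lx, ly = layout.usable_size
    if pitch > ly:
        raise GridConfigError("pitch exceeds the usable band height")
    n = int(np.floor(ly / pitch + 1e-9))
    y0 = layout.usable_origin[1]
    line_ys = y0 + pitch / 2.0 + np.arange(n) * pitch
    return LineGrid(
        pitch=pitch,
        tolerance=tolerance,
        line_ys=line_ys,
        travel_length=float(lx if travel_length is None else travel_length),
        x_start=layout.usable_origin[0],
    )


def _nearest_line_indices(ys: np.ndarray, grid: LineGrid) -> np.ndarray:
    # index of nearest line; exact midway ties break to the lower index
    f = (ys - grid.line_ys[0]) / grid.pitch
    k = np.ceil(f - 0.5 - 1e-12).astype(int)
    return np.clip(k, 0, grid.n - 1)


def assign_targets(
    targets: Sequence[CellTarget], grid: LineGrid
) -> list[LinePlan]:
    """Assign every target to its nearest scan line; skip empty lines.

    Returns one :class:`LinePlan` per line that received at least one
    target, in ascending line-index order, triggers in ascending x.
    Targets at identical x on the same line merge into one trigger event.

    Raises
    ------
    TargetOutOfBandError
        If a target lies outside the scanned band or the line extent,
        naming the offending id(s).
    """
    if not targets:
        return []
    ids = np.array([t.id for t in targets])
    xs = np.array([t.x for t in targets], dtype=float)
    ys = np.array([t.y for t in targets], dtype=float)
    y_lo = grid.line_ys[0] - grid.pitch / 2.0
    y_hi = grid.line_ys[-1] + grid.pitch / 2.0
    bad = (ys < y_lo - 1e-12) | (ys > y_hi + 1e-12)
    bad |= (xs < grid.x_start - 1e-12) | (xs > grid.x_end + 1e-12)
    if np.any(bad):
        raise TargetOutOfBandError(
            f"targets outside the scanned band: ids {ids[bad].tolist()}"
        )
    k = _nearest_line_indices(ys, grid)
    plans: list[LinePlan] = []
    for line_idx in np.unique(k):
        sel = np.flatnonzero(k == line_idx)
        y_line = float(grid.line_ys[line_idx])
        order = sel[np.lexsort((ids[sel], xs[sel]))]
        triggers: list[TriggerEvent] = []
        for j in order:
            xj = float(xs[j])
            err = abs(float(ys[j]) - y_line)
            if triggers and triggers[-1].x == xj:
                triggers[-1].target_ids += (int(ids[j]),)
                triggers[-1].lateral_error = max(triggers[-1].lateral_error, err)
            else:
                triggers.append(
                    TriggerEvent(
                        target_ids=(int(ids[j]),),
                        x=xj,
                        y_line=y_line,
                        lateral_error=err,
                    )
                )
        plans.append(LinePlan(line_index=int(line_idx), y=y_line, triggers=triggers))
    return plans


def plan_serpentine(plans: Iterable[LinePlan]) -> list[LinePlan]:
    """Alternate traversal direction over the visited lines.

    Visited lines keep ascending index order; directions alternate
    +x, -x, +x, ... over the *visited* lines (skipped lines do not flip
    the direction).  Trigger order within each line is re-sorted to match
    its traversal direction.
    """
    out: list[LinePlan] = []
    for j, plan in enumerate(sorted(plans, key=lambda p: p.line_index)):
        direction = +1 if j % 2 == 0 else -1
        triggers = sorted(plan.triggers, key=lambda tr: tr.x, reverse=direction < 0)
        out.append(replace(plan, direction=direction, triggers=triggers))
    return out


def trigger_time(
    x, grid: LineGrid, kin: StageKinematics, direction: int = +1
):
    """Time from line start at which the stage reaches position ``x``.

    Uses the accelerate-(cruise)-decelerate profile over the full line
    length; strictly increasing along the traversal with t = 0 at the
    line start and t = t_line at its end.
    """
    xa = np.asarray(x, dtype=float)
    if direction >= 0:
        s = xa - grid.x_start
    else:
        s = grid.x_end - xa
    return time_at_distance(s, grid.travel_length, kin)


def schedule_continuous(
    plans: Sequence[LinePlan],
    grid: LineGrid,
    kin: StageKinematics,
    t_switch: float = 0.04,
    pause: float = 0.0,
    t_line: float | None = None,
) -> ContinuousSchedule:
    """Time-stamp a serpentine plan and total up the scan duration.

    Line j (0-based among visited lines) starts at
    ``j * (t_line + pause + t_switch)``; each trigger's ``t_offset``
    comes from :func:`trigger_time` and its ``t_absolute`` adds the line
    start.  ``t_line`` defaults to the move time over the grid's travel
    length but may be overridden (e.g. to replay a published value).
    """
    if t_line is None:
        t_line = float(move_time_1d(grid.travel_length, kin))
    plans = list(plans)
    v = len(plans)
    starts: list[float] = []
    step = t_line + pause + t_switch
    for j, plan in enumerate(plans):
        start = j * step
        starts.append(start)
        if plan.triggers:
            xs = np.array([tr.x for tr in plan.triggers])
            ts = np.atleast_1d(trigger_time(xs, grid, kin, plan.direction))
            for tr, toff in zip(plan.triggers, ts):
                tr.t_offset = float(toff)
                tr.t_absolute = start + float(toff)
    total = v * (t_line + pause) + max(v - 1, 0) * t_switch
    return ContinuousSchedule(
        visited_lines=v,
        t_line=t_line,
        t_switch=t_switch,
        pause=pause,
        total_time=total,
        plans=plans,
        line_start_times=starts,
    )


def continuous_total_time(
    targets: Sequence[CellTarget],
    grid: LineGrid,
    kin: StageKinematics,
    t_switch: float = 0.04,
    pause: float = 0.0,
    t_line: float | None = None,
) -> float:
    """Total continuous-scan time without building per-trigger plans.

    Equivalent to ``schedule_continuous(...).total_time``: the total
    depends only on how many lines are visited, so it suffices to count
    distinct nearest-line indices.  Used by the Monte-Carlo comparison
    where only totals matter.
    """
    if t_line is None:
        t_line = float(move_time_1d(grid.travel_length, kin))
    if not targets:
        return 0.0
    ys = np.array([t.y for t in targets], dtype=float)
    v = len(np.unique(_nearest_line_indices(ys, grid)))
    return v * (t_line + pause) + max(v - 1, 0) * t_switch


def throughput_time(n_cells: int, rate: float) -> float:
    """Idealized transfer time at a fixed per-cell rate: ``n / rate`` (s)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    return n_cells / rate


def min_separation_violations(
    schedule: ContinuousSchedule, min_separation_um: float
) -> list[tuple[int, int, int]]:
    """Diagnostic for closely spaced firings on a line.

    Neighbouring LIFT events can interact; this reports
    ``(line_index, i, i+1)`` for consecutive triggers on a line whose
    along-track spacing is below ``min_separation_um``.  It does not
    alter the schedule (no firing rule is modelled); with the default
    configuration of 0 the check is off.
    """
    out: list[tuple[int, int, int]] = []
    if min_separation_um <= 0:
        return out
    sep_mm = min_separation_um * 1e-3
    for plan in schedule.plans:
        for i in range(len(plan.triggers) - 1):
            if abs(plan.triggers[i + 1].x - plan.triggers[i].x) < sep_mm:
                out.append((plan.line_index, i, i + 1))
    return out


def write_schedule_csv(schedule: ContinuousSchedule, lines_path, triggers_path) -> None:
    """Export a schedule as two CSVs: per-line summary and trigger list."""
    import pandas as pd

    lines = pd.DataFrame(
        {
            "line_index": [p.line_index for p in schedule.plans],
            "y_mm": [p.y for p in schedule.plans],
            "direction": ["+x" if p.direction > 0 else "-x" for p in schedule.plans],
            "start_time_s": schedule.line_start_times,
        }
    )
    lines.to_csv(lines_path, index=False)
    rows = []
    for plan in schedule.plans:
        for tr in plan.triggers:
            for tid in tr.target_ids:
                rows.append(
                    {
                        "target_id": tid,
                        "x_mm": tr.x,
                        "y_line_mm": tr.y_line,
                        "t_absolute_s": tr.t_absolute,
                        "lateral_error_um": tr.lateral_error * 1e3,
                    }
                )
    pd.DataFrame(
        rows,
        columns=["target_id", "x_mm", "y_line_mm", "t_absolute_s", "lateral_error_um"],
    ).to_csv(triggers_path, index=False)
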