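"""Task-parallel interpolation engine.

The unit of work is one target location across every day of the study period:
workers draw tasks from a shared queue over a read-only station tree, and the
interpolations are mutually independent, so the run is embarrassingly
parallel. Results are reassembled by task index before output, making the
output invariant to the worker count.
"""

from __future__ import annotations

import logging
import os
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core import AxisScales, IdwConfig, PredictionRecord, TargetSite, interpolate_point
from .errors import InvalidRangeError, NoDataError, TaskError
from .kdtree import KdTree

__all__ = ["TaskPlan", "RunConfig", "plan_tasks", "run"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskPlan:
    """Ordered list of (target, day-range) tasks, one per target."""

    tasks: tuple[tuple[TargetSite, range], ...]

    @property
    def total_predictions(self) -> int:
        return sum(len(days) for _, days in self.tasks)


@dataclass(frozen=True)
class RunConfig:
    """Worker pool size and how many tasks form one work unit."""

    n_workers: int = field(default_factory=lambda: os.cpu_count() or 1)
    chunking: int = 1

    def __post_init__(self):
        if self.n_workers < 1:
            raise ValueError(f"n_workers must be >= 1, got {self.n_workers}")
        if self.chunking < 1:
            raise ValueError(f"chunking must be >= 1, got {self.chunking}")


def plan_tasks(targets: Sequence[TargetSite], days: range) -> TaskPlan:
    """One task per target covering every day of ``days``.

    An empty target list yields an empty plan; an empty day range is an
    error (there would be nothing to interpolate for any target).
    """
    if len(days) == 0:
        raise InvalidRangeError("empty day range")
    return TaskPlan(tuple((t, days) for t in targets))


def run(plan: TaskPlan, tree: KdTree, config: IdwConfig, scales: AxisScales,
        run_config: RunConfig | None = None,
        progress: Callable[[int], None] | None = None
        ) -> list[PredictionRecord]:
    """Execute a plan; output ordered by (target input order, day ascending).

    The ordering and content are identical for any worker count: workers
    share the immutable tree, and results are collected per task and
    concatenated in plan order. A failing task surfaces as :class:`TaskError`
    naming the task. ``progress(task_index)`` is called as each task
    completes.
    """
    if tree.size == 0:
        raise NoDataError("run over a tree with no data")
    if run_config is None:
        run_config = RunConfig()
    n_tasks = len(plan.tasks)
    if n_tasks == 0:
        return []
    started = time.monotonic()
    log_every = max(1, n_tasks // 10)
    done = 0

    def do_task(index: int) -> list[PredictionRecord]:
        target, days = plan.tasks[index]
        try:
            return [
                interpolate_point(tree, (target.x, target.y, day), config,
                                  scales, target_id=target.target_id)
                for day in days
            ]
        except Exception as exc:  # noqa: BLE001 - re-raised with task identity
            raise TaskError(index, target.target_id, str(exc)) from exc

    def do_chunk(indices: Sequence[int]) -> list[list[PredictionRecord]]:
        return [do_task(i) for i in indices]

    chunk = run_config.chunking
    chunks = [range(i, min(i + chunk, n_tasks)) for i in range(0, n_tasks, chunk)]
    per_task: list[list[PredictionRecord] | None] = [None] * n_tasks
    with ThreadPoolExecutor(max_workers=run_config.n_workers) as pool:
        futures = [pool.submit(do_chunk, c) for c in chunks]
        for c, fut in zip(chunks, futures):
            for i, records in zip(c, fut.result()):
                per_task[i] = records
                done += 1
                if progress is not None:
                    progress(i)
                if done % log_every == 0 or done == n_tasks:
                    rate = done / max(time.monotonic() - started, 1e-9)
                    log.info("interpolated %d/%d tasks (%.1f tasks/s)",
                             done, n_tasks, rate)
    out: list[PredictionRecord] = []
    for records in per_task:
        assert records is not None
        out.extend(records)
    return out
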