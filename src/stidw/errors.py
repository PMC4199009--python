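"""Exception hierarchy for the stidw package."""


class StidwError(Exception):
    """Base class for all stidw errors."""


class InvalidExtentError(StidwError):
    """Degenerate spatial extent or too-short time span for the scale factor."""


class NoNeighborsError(StidwError):
    """An IDW value was requested with an empty neighbor list."""


class NoDataError(StidwError):
    """An operation was attempted on an empty tree/dataset."""


class DimensionMismatchError(StidwError):
    """Points of inconsistent dimensionality were supplied to the k-d tree."""


class NoEvaluablePairsError(StidwError):
    """No usable (interpolated, observed) pairs remain for an error statistic."""


class InsufficientDataError(StidwError):
    """Fewer records than a cross-validation scheme requires."""


class InvalidFoldsError(StidwError):
    """Fold count out of range for the dataset."""


class InvalidDayError(StidwError):
    """A day index outside the valid range was supplied."""


class InvalidRangeError(StidwError):
    """An empty or invalid day range was supplied to the task planner."""


class SchemaError(StidwError):
    """A required column is missing, or the input table is empty."""


class RowError(StidwError):
    """A row failed to parse; carries the 1-based line number of the file."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class TaskError(StidwError):
    """A worker task failed; identifies the offending task."""

    def __init__(self, task_index: int, target_id, message: str = ""):
        self.task_index = task_index
        self.target_id = target_id
        detail = f": {message}" if message else ""
        super().__init__(
            f"task {task_index} (target {target_id!r}) failed{detail}"
        )
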