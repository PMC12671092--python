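"""Memory-budget planning: translate byte budgets into a partition/batch plan.

Two budgets govern a run:

* the *system RAM* budget bounds how many samples of matrix B are resident at
  once (an "iteration" of the memory-aware loading strategy);
* the *device* budget bounds what fits on an accelerator (or, for the CPU
  reference backend, in a working-set cap). At most ``a_fraction`` (default
  70%) of the usable device budget is pre-allocated for matrix A; if A exceeds
  that threshold it is partitioned along the microbe axis and partial products
  are accumulated. The remaining budget batches matrix B along the sample
  axis.

All sizes are computed from a dense single-precision footprint model
(``rows x cols x 4`` bytes, GiB = 2**30 bytes), which reproduces the published
sizes of the standard 16S reference GCNs (e.g. ~5.12 GiB for a
13,839-function x 99,322-microbe matrix).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InsufficientBudgetError, PlanError

__all__ = [
    "estimate_dense_footprint",
    "recommend_iteration_size",
    "plan",
    "MemoryPlan",
    "ITERATION_ANCHORS",
]

GIB = 2**30

#: (system RAM in GiB, recommended samples per iteration). Linear at
#: 1,562.5 samples/GiB from 32 GiB upward; the 16 GiB anchor is a special case.
ITERATION_ANCHORS: tuple[tuple[float, int], ...] = (
    (16, 10_000),
    (32, 50_000),
    (64, 100_000),
    (128, 200_000),
    (256, 400_000),
    (384, 600_000),
    (512, 800_000),
    (640, 1_000_000),
)

_SAMPLES_PER_GIB = 1_562.5  # slope of the anchor table from 32 GiB upward


def estimate_dense_footprint(
    n_rows: int, n_cols: int, bytes_per_element: int = 4
) -> tuple[int, float]:
    """Dense matrix footprint as (exact bytes, GiB rounded to 2 decimals)."""
    if n_rows < 0 or n_cols < 0 or bytes_per_element < 1:
        raise PlanError("dimensions must be non-negative and element size positive")
    nbytes = int(n_rows) * int(n_cols) * int(bytes_per_element)
    return nbytes, round(nbytes / GIB, 2)


def recommend_iteration_size(ram_gib: float) -> int:
    """Samples per iteration recommended for a given system RAM budget.

    Piecewise-linear through the anchor table, clamped at the 16 GiB anchor
    below, extrapolated at 1,562.5 samples/GiB above 640 GiB, and rounded
    down to a multiple of 1,000.
    """
    if not ram_gib > 0:
        raise PlanError(f"ram_gib must be positive, got {ram_gib}")
    lo_ram, lo_val = ITERATION_ANCHORS[0]
    hi_ram, hi_val = ITERATION_ANCHORS[-1]
    if ram_gib <= lo_ram:
        samples = float(lo_val)
    elif ram_gib >= hi_ram:
        samples = ram_gib * _SAMPLES_PER_GIB
    else:
        for (r0, v0), (r1, v1) in zip(ITERATION_ANCHORS, ITERATION_ANCHORS[1:]):
            if r0 <= ram_gib <= r1:
                samples = v0 + (v1 - v0) * (ram_gib - r0) / (r1 - r0)
                break
    return int(samples // 1000) * 1000


@dataclass
class MemoryPlan:
    """A concrete execution plan for one streamed inference run.

    ``a_partitions`` are half-open ``[start, stop)`` ranges over the microbe
    axis that tile it exactly; each partition's dense footprint fits within
    ``a_fraction`` of the usable device budget.
    """

    iteration_size: int
    a_partitions: list[tuple[int, int]]
    b_batch_size: int
    n_workers: int = 1
    device_budget_bytes: int = 0
    reserve_fraction: float = 0.05
    a_fraction: float = 0.70
    bytes_per_element: int = 4
    n_functions: int = field(default=0)
    n_microbes: int = field(default=0)
    n_samples: int = field(default=0)

    def __post_init__(self) -> None:
        if self.iteration_size < 1:
            raise PlanError("iteration_size must be >= 1")
        if self.b_batch_size < 1:
            raise PlanError("b_batch_size must be >= 1")
        if self.n_workers < 1:
            raise PlanError("n_workers must be >= 1")
        if not (0 <= self.reserve_fraction < 1):
            raise PlanError("reserve_fraction must be in [0, 1)")
        if not (0 < self.a_fraction <= 1):
            raise PlanError("a_fraction must be in (0, 1]")
        self._check_partitions()

    def _check_partitions(self) -> None:
        if not self.a_partitions:
            raise PlanError("a_partitions must be non-empty")
        pos = 0
        for start, stop in self.a_partitions:
            if start != pos or stop <= start:
                raise PlanError(
                    f"a_partitions must be contiguous, disjoint half-open ranges; "
                    f"got {self.a_partitions}"
                )
            pos = stop
        if self.n_microbes == 0:
            self.n_microbes = pos
        elif pos != self.n_microbes:
            raise PlanError(
                f"a_partitions cover [0, {pos}) but n_microbes = {self.n_microbes}"
            )

    @property
    def n_a_partitions(self) -> int:
        return len(self.a_partitions)

    @property
    def usable_device_bytes(self) -> int:
        return int(self.device_budget_bytes * (1 - self.reserve_fraction))

    @classmethod
    def manual(
        cls,
        n_microbes: int,
        n_partitions: int,
        b_batch_size: int,
        iteration_size: int,
        n_workers: int = 1,
    ) -> "MemoryPlan":
        """Build a plan from explicit partition/batch counts (no byte budgets).

        Mostly useful for testing and for users who already know their split.
        """
        if not 1 <= n_partitions <= max(1, n_microbes):
            raise PlanError(f"n_partitions must be in [1, {n_microbes}]")
        return cls(
            iteration_size=iteration_size,
            a_partitions=_split_ranges(n_microbes, n_partitions),
            b_batch_size=b_batch_size,
            n_workers=n_workers,
            n_microbes=n_microbes,
        )

    def describe(self) -> dict:
        """Machine-readable plan summary (the CLI renders this as JSON)."""
        return {
            "iteration_size": self.iteration_size,
            "n_a_partitions": self.n_a_partitions,
            "a_partitions": [list(p) for p in self.a_partitions],
            "b_batch_size": self.b_batch_size,
            "n_workers": self.n_workers,
            "device_budget_bytes": self.device_budget_bytes,
            "usable_device_bytes": self.usable_device_bytes,
            "reserve_fraction": self.reserve_fraction,
            "a_fraction": self.a_fraction,
            "bytes_per_element": self.bytes_per_element,
            "n_functions": self.n_functions,
            "n_microbes": self.n_microbes,
            "n_samples": self.n_samples,
        }


def _split_ranges(n: int, parts: int) -> list[tuple[int, int]]:
    """Split [0, n) into `parts` near-equal contiguous ranges (remainder first)."""
    if n == 0:
        return [(0, 0)] if parts == 1 else []
    base, rem = divmod(n, parts)
    ranges = []
    pos = 0
    for i in range(parts):
        size = base + (1 if i < rem else 0)
        ranges.append((pos, pos + size))
        pos += size
    return ranges


def plan(
    a_dims: tuple[int, int],
    n_samples: int,
    device_budget_bytes: int,
    ram_gib: float,
    n_workers: int = 1,
    reserve_fraction: float = 0.05,
    a_fraction: float = 0.70,
    bytes_per_element: int = 4,
) -> MemoryPlan:
    """Derive a full :class:`MemoryPlan` from budgets and matrix dimensions.

    Parameters
    ----------
    a_dims:
        (n_functions, n_microbes) of matrix A.
    n_samples:
        Total number of samples in matrix B.
    device_budget_bytes:
        Total device (or working-set) budget; a ``reserve_fraction`` is held
        back for intermediates, at most ``a_fraction`` of the remainder is
        pre-allocated for A.
    ram_gib:
        System RAM budget driving the samples-per-iteration recommendation.

    The number of A-partitions is the smallest count whose largest partition
    fits the A budget; per-sample batch cost counts both the B row-slice and
    the C accumulator column so batches provably fit in the leftover budget.
    """
    n_functions, n_microbes = a_dims
    if n_functions < 1 or n_microbes < 1:
        raise PlanError("matrix A must have positive dimensions")
    if n_samples < 0:
        raise PlanError("n_samples must be non-negative")
    if device_budget_bytes <= 0:
        raise PlanError("device budget must be positive")

    usable = int(device_budget_bytes * (1 - reserve_fraction))
    a_budget = int(a_fraction * usable)
    col_bytes = n_functions * bytes_per_element  # one microbe column of A

    max_cols = a_budget // col_bytes
    if max_cols < 1:
        raise InsufficientBudgetError(
            "insufficient device budget: a single microbe column of A "
            f"({col_bytes} B) exceeds the A budget ({a_budget} B)"
        )
    n_parts = math.ceil(n_microbes / max_cols)
    partitions = _split_ranges(n_microbes, n_parts)
    max_part_cols = max(stop - start for start, stop in partitions)
    a_part_bytes = max_part_cols * col_bytes

    per_sample_bytes = bytes_per_element * (max_part_cols + n_functions)
    leftover = usable - a_part_bytes
    if leftover < bytes_per_element * (1 + n_functions):
        raise InsufficientBudgetError(
            "insufficient device budget: cannot hold one microbe column of A "
            "plus one sample of B and C"
        )
    b_batch_size = max(1, leftover // per_sample_bytes)

    rec = recommend_iteration_size(ram_gib)
    iteration_size = rec if n_samples == 0 else max(1, min(rec, n_samples))

    return MemoryPlan(
        iteration_size=iteration_size,
        a_partitions=partitions,
        b_batch_size=int(b_batch_size),
        n_workers=n_workers,
        device_budget_bytes=device_budget_bytes,
        reserve_fraction=reserve_fraction,
        a_fraction=a_fraction,
        bytes_per_element=bytes_per_element,
        n_functions=n_functions,
        n_microbes=n_microbes,
        n_samples=n_samples,
    )
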