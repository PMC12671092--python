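"""Core functional inference: C[i][j] = sum_k A[i][k] * B[k][j].

Two execution paths share one contract:

* :func:`infer_dense` — one call into BLAS; the reference result.
* :func:`infer_streamed` — the same product computed out-of-core: samples are
  loaded in RAM-bounded iterations, matrix A is processed partition by
  partition along the microbe axis, and each partition stage multiplies
  sample batches (optionally on several workers) into a per-column
  accumulator. Accumulation over partitions is in ascending partition index,
  so the result is deterministic and independent of the worker count; the
  degenerate one-partition/one-batch plan is bit-identical to the dense path.

The multiply primitive itself is pluggable (``backend``): the portable dense
NumPy implementation is the required reference; an accelerated drop-in (e.g.
a GPU array library) only has to implement "multiply a functions x k block by
a k x samples block" and pass the same oracle suite.
"""
from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Literal, Mapping, Union

import numpy as np

from .containers import AbundanceTable, FunctionMicrobeMatrix, FunctionProfileMatrix
from .errors import PlanError, ValidationError
from .planning import MemoryPlan

logger = logging.getLogger("microfunc")

__all__ = [
    "infer_dense",
    "infer_streamed",
    "align_microbes",
    "AlignmentReport",
    "schedule",
    "run_concurrent",
    "WorkUnit",
    "normalize_by_marker_copy_number",
    "BACKENDS",
]

#: name -> block-multiply implementation ``(A_block, B_block) -> C_block``.
BACKENDS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "reference": lambda a, b: a @ b,
}


def _resolve_backend(backend) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    if callable(backend):
        return backend
    try:
        return BACKENDS[backend]
    except KeyError:
        raise ValidationError(
            f"unknown backend {backend!r}; available: {sorted(BACKENDS)}"
        ) from None


def infer_dense(A: FunctionMicrobeMatrix, B: AbundanceTable) -> FunctionProfileMatrix:
    """Reference inference: one dense multiplication of reconciled A and B."""
    if A.microbe_ids != B.microbe_ids:
        raise ValidationError(
            "microbe axes of A and B are not reconciled; call align_microbes first"
        )
    return FunctionProfileMatrix(
        list(A.function_ids), list(B.sample_ids), A.values @ B.values
    )


@dataclass(frozen=True)
class AlignmentReport:
    """What :func:`align_microbes` dropped (empty under strict success)."""

    dropped_microbe_ids: tuple[str, ...] = ()
    dropped_abundance_fraction: float = 0.0
    n_kept: int = 0

    @property
    def empty(self) -> bool:
        return not self.dropped_microbe_ids


def align_microbes(
    A: FunctionMicrobeMatrix,
    B: AbundanceTable,
    policy: Literal["strict", "intersect"] = "strict",
) -> tuple[FunctionMicrobeMatrix, AbundanceTable, AlignmentReport]:
    """Reconcile the microbe axes of A and B.

    ``strict`` errors if any microbe of B is absent from A; ``intersect``
    drops absent microbes and reports the dropped fraction of total abundance.
    A's columns are selected in B's microbe order either way.
    """
    if policy not in ("strict", "intersect"):
        raise ValidationError(f"unknown alignment policy {policy!r}")
    known = set(A.microbe_ids)
    missing = [m for m in B.microbe_ids if m not in known]
    if missing:
        if policy == "strict":
            raise ValidationError(
                f"{len(missing)} microbe(s) of B absent from the GCN: {missing[:10]}"
            )
        kept = [m for m in B.microbe_ids if m in known]
        if not kept:
            raise ValidationError("intersect alignment left zero microbes")
        total = float(B.values.sum())
        keep_mask = np.array([m in known for m in B.microbe_ids])
        dropped_abundance = float(B.values[~keep_mask].sum())
        report = AlignmentReport(
            dropped_microbe_ids=tuple(missing),
            dropped_abundance_fraction=(dropped_abundance / total) if total > 0 else 0.0,
            n_kept=len(kept),
        )
        logger.warning(
            "alignment dropped %d microbe(s) carrying %.4f of total abundance",
            len(missing), report.dropped_abundance_fraction,
        )
        B = B.select_microbes(kept)
    else:
        report = AlignmentReport(n_kept=B.n_microbes)
    return A.select_microbes(B.microbe_ids), B, report


def normalize_by_marker_copy_number(
    B: AbundanceTable, copy_numbers: Mapping[str, float]
) -> AbundanceTable:
    """Divide each microbe's abundances by its 16S marker copy number.

    Optional pre-inference step (off by default in the CLI): corrects for
    multi-copy marker genes inflating apparent abundance.
    """
    divisors = np.empty(B.n_microbes)
    for k, mid in enumerate(B.microbe_ids):
        cn = copy_numbers.get(mid)
        if cn is None:
            raise ValidationError(f"missing marker copy number for microbe {mid!r}")
        if not cn > 0:
            raise ValidationError(f"non-positive marker copy number for microbe {mid!r}")
        divisors[k] = cn
    return AbundanceTable(
        list(B.microbe_ids), list(B.sample_ids), B.values / divisors[:, None]
    )


@dataclass(frozen=True, order=True)
class WorkUnit:
    """One (A-partition, sample-batch) multiplication assigned to a worker."""

    a_partition_index: int
    sample_batch_range: tuple[int, int]
    worker_id: int


def schedule(plan: MemoryPlan, n_partitions: int, n_samples: int) -> list[WorkUnit]:
    """Enumerate work units for one resident iteration of ``n_samples`` samples.

    Within each A-partition stage, sample batches are assigned round-robin
    over workers (remainders to lower worker ids); stages are ordered by
    ascending partition index and separated by a barrier at execution time,
    so every worker holds the same A-partition at any moment.
    """
    if plan.n_workers < 1:
        raise PlanError("n_workers must be >= 1")
    batches = [
        (s, min(s + plan.b_batch_size, n_samples))
        for s in range(0, n_samples, plan.b_batch_size)
    ]
    return [
        WorkUnit(p, batch, i % plan.n_workers)
        for p in range(n_partitions)
        for i, batch in enumerate(batches)
    ]


def run_concurrent(
    A: FunctionMicrobeMatrix,
    B: AbundanceTable,
    plan: MemoryPlan,
    units: Iterable[WorkUnit] | None = None,
    executor_width: int | None = None,
    backend="reference",
    out: np.ndarray | None = None,
) -> FunctionProfileMatrix:
    """Execute scheduled work units over one resident iteration of B.

    The result is independent of ``executor_width``: units within a stage
    write disjoint sample-column blocks, stages are barriered, and each
    column block accumulates partitions in ascending index, so the floating
    point accumulation order is fixed by the plan alone.
    """
    mult = _resolve_backend(backend)
    if A.microbe_ids != B.microbe_ids:
        raise ValidationError("microbe axes of A and B are not reconciled")
    if plan.a_partitions[-1][1] != A.n_microbes:
        raise PlanError(
            f"plan covers {plan.a_partitions[-1][1]} microbes, matrix has {A.n_microbes}"
        )
    if units is None:
        units = schedule(plan, plan.n_a_partitions, B.n_samples)
    units = sorted(units)
    _check_coverage(units, plan.n_a_partitions, B.n_samples, plan.b_batch_size)

    C = out if out is not None else np.zeros((A.n_functions, B.n_samples))
    width = executor_width if executor_width is not None else plan.n_workers

    def run_unit(unit: WorkUnit) -> None:
        p0, p1 = plan.a_partitions[unit.a_partition_index]
        c0, c1 = unit.sample_batch_range
        partial = mult(A.values[:, p0:p1], B.values[p0:p1, c0:c1])
        if unit.a_partition_index == 0:
            C[:, c0:c1] = partial
        else:
            C[:, c0:c1] += partial

    by_stage: dict[int, list[WorkUnit]] = {}
    for u in units:
        by_stage.setdefault(u.a_partition_index, []).append(u)

    if width == 1:
        for p in sorted(by_stage):
            for u in by_stage[p]:
                _run_with_context(run_unit, u)
    else:
        with ThreadPoolExecutor(max_workers=width) as pool:
            for p in sorted(by_stage):  # barrier between partition stages
                futures = [pool.submit(_run_with_context, run_unit, u) for u in by_stage[p]]
                for f in futures:
                    f.result()
    return FunctionProfileMatrix(list(A.function_ids), list(B.sample_ids), C)


def _run_with_context(fn, unit: WorkUnit) -> None:
    try:
        fn(unit)
    except Exception as exc:  # noqa: BLE001 - re-raise with unit context
        raise RuntimeError(
            f"worker {unit.worker_id} failed on partition "
            f"{unit.a_partition_index}, samples {unit.sample_batch_range}: {exc}"
        ) from exc


def _check_coverage(
    units: list[WorkUnit], n_partitions: int, n_samples: int, b_batch_size: int
) -> None:
    expected = {
        (p, (s, min(s + b_batch_size, n_samples)))
        for p in range(n_partitions)
        for s in range(0, n_samples, b_batch_size)
    }
    got = [(u.a_partition_index, u.sample_batch_range) for u in units]
    if len(got) != len(set(got)) or set(got) != expected:
        raise PlanError("work units do not cover every (partition, batch) exactly once")


BSource = Union[AbundanceTable, Iterable[AbundanceTable]]


def _iterations(b_source: BSource, iteration_size: int) -> Iterator[AbundanceTable]:
    if isinstance(b_source, AbundanceTable):
        n = b_source.n_samples
        start = 0
        while start < n:
            stop = min(start + iteration_size, n)
            logger.debug("iteration: samples [%d, %d) of %d", start, stop, n)
            yield b_source.select_samples(start, stop)
            start = stop
        if n == 0:
            return
    else:
        for chunk in b_source:
            if chunk.n_samples > iteration_size:
                # an external source may ignore the plan; re-slice defensively
                yield from _iterations(chunk, iteration_size)
            else:
                yield chunk


def infer_streamed(
    a_source: FunctionMicrobeMatrix,
    b_source: BSource,
    plan: MemoryPlan,
    backend="reference",
    executor_width: int | None = None,
) -> FunctionProfileMatrix:
    """Out-of-core inference equivalent to :func:`infer_dense`.

    ``b_source`` is either a resident :class:`AbundanceTable` (sliced into
    iterations of at most ``plan.iteration_size`` samples) or any iterable of
    chunks (e.g. :func:`microfunc.io_formats.iter_abundance_chunks` streaming
    from disk). At most ``iteration_size`` samples are resident at a time.
    """
    A = a_source
    if plan.a_partitions[-1][1] != A.n_microbes:
        raise PlanError(
            f"plan partitions cover {plan.a_partitions[-1][1]} microbes, "
            f"matrix A has {A.n_microbes}"
        )
    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    for chunk in _iterations(b_source, plan.iteration_size):
        if chunk.microbe_ids != A.microbe_ids:
            raise ValidationError("microbe axes of A and a B chunk are not reconciled")
        result = run_concurrent(
            A, chunk, plan, executor_width=executor_width, backend=backend
        )
        blocks.append(result.values)
        sample_ids.extend(result.sample_ids)
    if blocks:
        values = blocks[0] if len(blocks) == 1 else np.concatenate(blocks, axis=1)
    else:
        values = np.zeros((A.n_functions, 0))
    return FunctionProfileMatrix(list(A.function_ids), sample_ids, values)
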