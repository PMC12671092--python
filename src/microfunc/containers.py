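"""In-memory containers for the three matrices of GCN-based function inference.

The method's core identity is ``C = A @ B`` where

* ``A`` (:class:`FunctionMicrobeMatrix`) holds gene-family copy numbers per
  reference microbe — functions x microbes,
* ``B`` (:class:`AbundanceTable`) holds per-sample microbe abundances —
  microbes x samples,
* ``C`` (:class:`FunctionProfileMatrix`) is the inferred functional profile —
  functions x samples.

All containers validate on construction: finite non-negative values,
unique identifiers, shapes consistent with the identifier axes. Values are
stored as ``float64`` C-contiguous arrays so that accumulation order — not
storage precision — is the only source of rounding differences between the
dense and the streamed execution paths.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "FunctionMicrobeMatrix",
    "AbundanceTable",
    "FunctionProfileMatrix",
    "PathwayMap",
]


def _check_ids(ids: Sequence[str], axis_name: str) -> list[str]:
    ids = [str(i) for i in ids]
    if any(i == "" for i in ids):
        raise ValidationError(f"empty identifier on {axis_name} axis")
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {axis_name} identifiers: {dups[:10]}")
    return ids


def _check_values(values, shape: tuple[int, int], what: str) -> np.ndarray:
    arr = np.ascontiguousarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"{what}: expected a 2-D matrix, got ndim={arr.ndim}")
    if arr.shape != shape:
        raise ValidationError(
            f"{what}: matrix shape {arr.shape} does not match identifier axes {shape}"
        )
    if arr.size and not np.isfinite(arr).all():
        raise ValidationError(f"{what}: non-finite values present")
    if arr.size and (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(f"{what}: negative value at row {i}, column {j}")
    return arr


@dataclass
class FunctionMicrobeMatrix:
    """Matrix A: gene copy number of each function (row) in each microbe (column)."""

    function_ids: list[str]
    microbe_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.function_ids = _check_ids(self.function_ids, "function")
        self.microbe_ids = _check_ids(self.microbe_ids, "microbe")
        self.values = _check_values(
            self.values, (len(self.function_ids), len(self.microbe_ids)), "GCN matrix"
        )

    @property
    def n_functions(self) -> int:
        return len(self.function_ids)

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    def select_microbes(self, microbe_ids: Sequence[str]) -> "FunctionMicrobeMatrix":
        """Column subset/reorder; every requested microbe must be present."""
        index = {m: k for k, m in enumerate(self.microbe_ids)}
        missing = [m for m in microbe_ids if m not in index]
        if missing:
            raise ValidationError(f"unknown microbes: {missing[:10]}")
        cols = [index[m] for m in microbe_ids]
        return FunctionMicrobeMatrix(
            list(self.function_ids), list(microbe_ids), self.values[:, cols]
        )


@dataclass
class AbundanceTable:
    """Matrix B: sequence count (or relative abundance) of each microbe per sample."""

    microbe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.microbe_ids = _check_ids(self.microbe_ids, "microbe")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = _check_values(
            self.values, (len(self.microbe_ids), len(self.sample_ids)), "abundance table"
        )

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_samples(self, start: int, stop: int) -> "AbundanceTable":
        """Contiguous sample slice [start, stop)."""
        return AbundanceTable(
            list(self.microbe_ids),
            self.sample_ids[start:stop],
            self.values[:, start:stop],
        )

    def select_microbes(self, microbe_ids: Sequence[str]) -> "AbundanceTable":
        index = {m: k for k, m in enumerate(self.microbe_ids)}
        missing = [m for m in microbe_ids if m not in index]
        if missing:
            raise ValidationError(f"unknown microbes: {missing[:10]}")
        rows = [index[m] for m in microbe_ids]
        return AbundanceTable(list(microbe_ids), list(self.sample_ids), self.values[rows, :])


@dataclass
class FunctionProfileMatrix:
    """Matrix C: inferred abundance of each function (row) in each sample (column).

    Also reused for any feature x sample matrix (e.g. pathway profiles).
    """

    function_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.function_ids = _check_ids(self.function_ids, "function")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = _check_values(
            self.values, (len(self.function_ids), len(self.sample_ids)), "function profile"
        )

    @property
    def n_functions(self) -> int:
        return len(self.function_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PathwayMap:
    """Many-to-many mapping from function identifier (KO) to pathway identifier."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for ko, pathways in self.entries.items():
            if not ko:
                raise ValidationError("empty function identifier in pathway map")
            pws = frozenset(str(p) for p in pathways)
            if any(p == "" for p in pws):
                raise ValidationError(f"empty pathway identifier for function {ko!r}")
            clean[str(ko)] = pws
        self.entries = clean

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PathwayMap":
        acc: dict[str, set[str]] = {}
        for ko, pw in pairs:
            acc.setdefault(ko, set()).add(pw)
        return cls({k: frozenset(v) for k, v in acc.items()})

    def pathways_of(self, ko: str) -> frozenset[str]:
        return self.entries.get(ko, frozenset())

    @property
    def pathway_ids(self) -> list[str]:
        out: set[str] = set()
        for pws in self.entries.values():
            out |= pws
        return sorted(out)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ko: object) -> bool:
        return ko in self.entries

    def as_mapping(self) -> Mapping[str, frozenset[str]]:
        return dict(self.entries)
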