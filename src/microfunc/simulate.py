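"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their parameters plus a seed, so a
whole fixture set (GCN, abundance table, tree, traits, pathway map) is
reproducible from one integer. Each generator folds a fixed offset into the
seed (``SeedSequence(seed, spawn_key=(offset,))``) so the same base seed can
drive several generators without stream collisions.

The fixtures exercise numerics and contracts — matrix shapes, sparsity,
non-negativity, phylogenetic trait smoothness — not community ecology.
"""
from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceTable, FunctionMicrobeMatrix, PathwayMap
from .errors import ValidationError

__all__ = [
    "make_gcn",
    "make_abundance_table",
    "make_tree_with_traits",
    "make_pathway_map",
    "make_nsti_distances",
    "stream_batches",
]

# per-generator seed offsets (documented convention)
_OFFSET_GCN = 0
_OFFSET_ABUNDANCE = 1
_OFFSET_TREE = 2
_OFFSET_PATHWAYS = 3
_OFFSET_NSTI = 4


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(offset,)))


def make_gcn(
    n_functions: int = 200,
    n_microbes: int = 500,
    density: float = 0.3,
    copy_max: int = 30,
    seed: int = 0,
) -> FunctionMicrobeMatrix:
    """Random sparse-ish gene copy-number matrix (functions x microbes).

    Non-zero entries are uniform integers in [1, copy_max]; the expected
    non-zero fraction is ``density``. Default dimensions are a desk-scale
    stand-in for real reference GCNs (which run to ~10^4 functions x 10^5
    microbes).
    """
    if not (0 < density <= 1):
        raise ValidationError("density must be in (0, 1]")
    if n_functions < 1 or n_microbes < 1 or copy_max < 1:
        raise ValidationError("dimensions and copy_max must be positive")
    rng = _rng(seed, _OFFSET_GCN)
    shape = (n_functions, n_microbes)
    mask = rng.random(shape) < density
    values = mask * rng.integers(1, copy_max + 1, size=shape)
    return FunctionMicrobeMatrix(
        [f"K{i:05d}" for i in range(n_functions)],
        [f"m{k:05d}" for k in range(n_microbes)],
        values.astype(np.float64),
    )


def make_abundance_table(
    n_microbes: int = 500,
    n_samples: int = 100,
    mean_depth: float = 10_000.0,
    sparsity: float = 0.5,
    seed: int = 0,
) -> AbundanceTable:
    """Random counts table: per-entry dropout, log-normal depth, no empty samples.

    Counts are log-normal draws rounded to integers with per-entry dropout at
    rate ``sparsity``; the expected per-sample total is ``mean_depth``.
    Samples that come out all-zero are redrawn so every sample is usable.
    """
    if n_microbes < 1 or n_samples < 1:
        raise ValidationError("dimensions must be positive")
    if not mean_depth > 0:
        raise ValidationError("mean_depth must be positive")
    if not (0 <= sparsity < 1):
        raise ValidationError("sparsity must be in [0, 1)")
    rng = _rng(seed, _OFFSET_ABUNDANCE)
    entry_mean = mean_depth / (n_microbes * (1.0 - sparsity))
    sigma = 1.0
    mu = np.log(entry_mean) - sigma**2 / 2.0

    def draw(n_cols: int) -> np.ndarray:
        keep = rng.random((n_microbes, n_cols)) >= sparsity
        counts = np.rint(rng.lognormal(mu, sigma, size=(n_microbes, n_cols)))
        return keep * counts

    values = draw(n_samples)
    empty = values.sum(axis=0) == 0
    while empty.any():  # redraw all-zero samples
        values[:, empty] = draw(int(empty.sum()))
        empty = values.sum(axis=0) == 0
    return AbundanceTable(
        [f"m{k:05d}" for k in range(n_microbes)],
        [f"s{j:05d}" for j in range(n_samples)],
        values,
    )


class _SimNode:
    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[_SimNode] = []
        self.length = length

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def make_tree_with_traits(
    n_refs: int = 40,
    n_queries: int = 10,
    trait_dim: int = 20,
    smoothness: float = 3.0,
    seed: int = 0,
    branch_scale: float = 0.1,
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Random bifurcating tree with phylogenetically smooth traits.

    Branch lengths are exponential with mean ``branch_scale``. Traits start
    from a uniform root vector and accumulate zero-mean Gaussian steps with
    standard deviation ``branch_length * smoothness`` down each edge, clipped
    at 0 — so phylogenetically close tips have similar trait vectors and a
    distance-weighted predictor can recover held-out tips.

    Returns ``(newick, reference trait table, true query traits)``; the query
    tips' true traits are the held-out ground truth for recovery tests.
    """
    n_tips = n_refs + n_queries
    if n_refs < 1 or n_queries < 0 or trait_dim < 1 or n_tips < 2:
        raise ValidationError("need >=1 reference, >=2 tips, >=1 trait dimension")
    rng = _rng(seed, _OFFSET_TREE)

    nodes = [_SimNode(f"t{i:04d}", float(rng.exponential(branch_scale))) for i in range(n_tips)]
    while len(nodes) > 1:  # random sequential joins -> random bifurcating topology
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _SimNode(None, float(rng.exponential(branch_scale)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0

    traits: dict[str, np.ndarray] = {}

    def evolve(node: _SimNode, state: np.ndarray) -> None:
        for child in node.children:
            step = rng.normal(0.0, max(child.length * smoothness, 1e-12), size=trait_dim)
            child_state = np.clip(state + step, 0.0, None)
            if child.children:
                evolve(child, child_state)
            else:
                traits[child.name] = child_state

    root_state = rng.uniform(2.0, 8.0, size=trait_dim)
    if root.children:
        evolve(root, root_state)
    else:
        traits[root.name] = root_state

    tip_names = sorted(traits)
    query_idx = set(rng.choice(n_tips, size=n_queries, replace=False).tolist())
    refs = [t for i, t in enumerate(tip_names) if i not in query_idx]
    queries = [t for i, t in enumerate(tip_names) if i in query_idx]
    columns = [f"K{i:05d}" for i in range(trait_dim)]
    ref_traits = pd.DataFrame([traits[t] for t in refs], index=refs, columns=columns)
    query_traits = pd.DataFrame([traits[t] for t in queries], index=queries, columns=columns)
    return root.newick() + ";", ref_traits, query_traits


def make_pathway_map(
    function_ids: Sequence[str],
    n_pathways: int = 8,
    mapped_fraction: float = 0.9,
    multi_fraction: float = 0.2,
    seed: int = 0,
) -> PathwayMap:
    """Random KO -> pathway map; some KOs unmapped, some in two pathways."""
    if n_pathways < 1:
        raise ValidationError("n_pathways must be positive")
    rng = _rng(seed, _OFFSET_PATHWAYS)
    pathways = [f"path{p:03d}" for p in range(n_pathways)]
    pairs: list[tuple[str, str]] = []
    for ko in function_ids:
        if rng.random() >= mapped_fraction:
            continue
        first = int(rng.integers(n_pathways))
        pairs.append((str(ko), pathways[first]))
        if n_pathways > 1 and rng.random() < multi_fraction:
            second = int(rng.integers(n_pathways - 1))
            if second >= first:
                second += 1
            pairs.append((str(ko), pathways[second]))
    return PathwayMap.from_pairs(pairs)


def make_nsti_distances(
    microbe_ids: Sequence[str],
    mean_distance: float = 0.05,
    reference_fraction: float = 0.3,
    seed: int = 0,
) -> dict[str, float]:
    """Exponentially distributed per-microbe NSTI distances.

    A ``reference_fraction`` of microbes sit at distance 0 (they are
    sequenced references themselves); the rest draw from an exponential with
    the given mean, matching the right-skewed shape of real NSTI values.
    """
    if not mean_distance > 0 or not (0 <= reference_fraction <= 1):
        raise ValidationError("mean_distance must be > 0, reference_fraction in [0, 1]")
    rng = _rng(seed, _OFFSET_NSTI)
    is_ref = rng.random(len(microbe_ids)) < reference_fraction
    d = rng.exponential(mean_distance, size=len(microbe_ids))
    return {
        str(m): 0.0 if ref else float(dist)
        for m, ref, dist in zip(microbe_ids, is_ref, d)
    }


def stream_batches(table_spec: dict, iteration_size: int) -> Iterator[AbundanceTable]:
    """Yield a generated abundance table in chunks of <= iteration_size samples.

    The concatenation of the chunks equals ``make_abundance_table(**table_spec)``.
    """
    if iteration_size < 1:
        raise ValidationError("iteration_size must be >= 1")
    table = make_abundance_table(**table_spec)
    for start in range(0, table.n_samples, iteration_size):
        yield table.select_samples(start, min(start + iteration_size, table.n_samples))
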