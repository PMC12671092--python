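"""Build a genome content network (GCN) from a phylogeny plus known traits.

The GCN links reference 16S sequences to whole-genome functional annotations.
For tips whose genomes are sequenced, gene-family copy numbers are known;
for other tips they are predicted by a distance-weighted hidden-state
prediction (HSP): a convex combination of reference trait vectors with
weights decreasing in patristic distance, so closer genomes receive higher
weight. Each predicted tip also carries its nearest-sequenced-taxon distance
(the per-microbe NSTI ingredient).

This is a deliberately simple HSP — a weighted average over references — not
a continuous-time Markov model ancestral reconstruction; see the methods
note for the trade-offs.
"""
from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import skbio

from .containers import FunctionMicrobeMatrix
from .errors import ValidationError

logger = logging.getLogger("microfunc")

__all__ = [
    "ReferenceRecord",
    "read_tree",
    "patristic_distance",
    "nearest_sequenced_distance",
    "hsp_weighted",
    "build_gcn",
    "collapse_identical",
    "read_trait_table",
    "write_trait_table",
]

#: regularizer added to distances under inverse-distance weighting
HSP_EPSILON = 1e-9

Weighting = Literal["inverse-distance", "exponential-decay"]


@dataclass(frozen=True)
class ReferenceRecord:
    """Per-microbe metadata attached to a GCN column.

    ``nsti_distance`` is the patristic distance to the nearest sequenced
    reference (0 iff the microbe is itself a reference).
    """

    microbe_id: str
    nsti_distance: float
    marker_copy_number: float | None = None
    nearest_reference: str | None = None

    def __post_init__(self) -> None:
        if self.nsti_distance < 0:
            raise ValidationError(
                f"negative NSTI distance for {self.microbe_id!r}"
            )
        if self.marker_copy_number is not None and not self.marker_copy_number > 0:
            raise ValidationError(
                f"non-positive marker copy number for {self.microbe_id!r}"
            )


def read_tree(source: Union[str, Path, skbio.TreeNode]) -> skbio.TreeNode:
    """Read a newick tree; branch lengths are required to be non-negative.

    ``source`` may be a path, a newick string, or an already-parsed tree.
    Trees are treated as unrooted for distance purposes (rooting does not
    change patristic distances).
    """
    if isinstance(source, skbio.TreeNode):
        tree = source
    else:
        text = str(source)
        if "(" in text:  # newick literal rather than a path
            tree = skbio.TreeNode.read(_io.StringIO(text))
        else:
            tree = skbio.TreeNode.read(str(source))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} at node {node.name!r}"
            )
    return tree


def _find_tip(tree: skbio.TreeNode, name: str) -> skbio.TreeNode:
    try:
        return tree.find(name)
    except skbio.tree.MissingNodeError:
        raise ValidationError(f"tip {name!r} not found in tree") from None


def patristic_distance(tree: skbio.TreeNode, tip_a: str, tip_b: str) -> float:
    """Sum of branch lengths on the path between two tips."""
    if tip_a == tip_b:
        _find_tip(tree, tip_a)
        return 0.0
    return float(_find_tip(tree, tip_a).distance(_find_tip(tree, tip_b)))


def _distance_row(
    tree: skbio.TreeNode, query_tip: str, others: Sequence[str]
) -> np.ndarray:
    """Distances from one tip to several others (single traversal each)."""
    q = _find_tip(tree, query_tip)
    return np.array(
        [0.0 if o == query_tip else float(q.distance(_find_tip(tree, o))) for o in others]
    )


def nearest_sequenced_distance(
    tree: skbio.TreeNode,
    query_tip: str,
    reference_tips: Sequence[str],
    _distances: np.ndarray | None = None,
) -> tuple[float, str]:
    """Minimum patristic distance from a tip to any sequenced reference.

    Ties are broken by the lexicographically smallest reference id.
    """
    refs = list(reference_tips)
    if not refs:
        raise ValidationError("reference set is empty")
    d = _distances if _distances is not None else _distance_row(tree, query_tip, refs)
    best = float(np.min(d))
    nearest = min(r for r, dr in zip(refs, d) if dr == best)
    return best, nearest


def hsp_weighted(
    tree: skbio.TreeNode,
    known: pd.DataFrame,
    query_tip: str,
    weighting: Weighting = "inverse-distance",
    _distances: np.ndarray | None = None,
) -> pd.Series:
    """Predict a tip's trait vector as a distance-weighted reference average.

    Parameters
    ----------
    known:
        Trait table on reference tips: rows = reference ids (must be tips of
        ``tree``), columns = gene families, non-negative copy numbers.
    weighting:
        ``inverse-distance`` (default): w_r = 1 / (d_r + 1e-9);
        ``exponential-decay``: w_r = exp(-d_r).
        If any reference sits at distance 0, the prediction is the plain mean
        over all zero-distance references.

    The prediction is a convex combination of reference rows, hence bounded
    elementwise by the reference minima and maxima.
    """
    if known.shape[0] == 0:
        raise ValidationError("no reference tips with traits")
    refs = [str(r) for r in known.index]
    d = _distances if _distances is not None else _distance_row(tree, query_tip, refs)
    traits = known.to_numpy(dtype=np.float64)
    if np.any(d == 0):
        w = (d == 0).astype(np.float64)
    elif weighting == "inverse-distance":
        w = 1.0 / (d + HSP_EPSILON)
    elif weighting == "exponential-decay":
        w = np.exp(-d)
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    pred = (w @ traits) / w.sum()
    return pd.Series(pred, index=known.columns, name=query_tip)


def build_gcn(
    tree: skbio.TreeNode,
    known_traits: pd.DataFrame,
    query_tips: Sequence[str],
    weighting: Weighting = "inverse-distance",
    marker_copy_numbers: Mapping[str, float] | None = None,
) -> tuple[FunctionMicrobeMatrix, list[ReferenceRecord]]:
    """Assemble matrix A over references and queries, plus NSTI records.

    References keep their known traits with NSTI distance 0; each query gets
    an HSP-predicted trait vector and its nearest-sequenced-taxon distance.
    """
    tree = read_tree(tree)
    refs = [str(r) for r in known_traits.index]
    if not refs:
        raise ValidationError("known_traits is empty")
    queries = [str(q) for q in query_tips]
    overlap = set(refs) & set(queries)
    if overlap:
        raise ValidationError(f"tips listed as both reference and query: {sorted(overlap)[:10]}")
    for r in refs:
        _find_tip(tree, r)

    columns: dict[str, np.ndarray] = {
        r: known_traits.loc[r].to_numpy(dtype=np.float64) for r in refs
    }
    records: list[ReferenceRecord] = [
        ReferenceRecord(
            r, 0.0,
            marker_copy_numbers.get(r) if marker_copy_numbers else None,
            nearest_reference=r,
        )
        for r in refs
    ]
    for q in queries:
        d = _distance_row(tree, q, refs)
        columns[q] = hsp_weighted(tree, known_traits, q, weighting, _distances=d).to_numpy()
        d_k, nearest = nearest_sequenced_distance(tree, q, refs, _distances=d)
        records.append(
            ReferenceRecord(
                q, d_k,
                marker_copy_numbers.get(q) if marker_copy_numbers else None,
                nearest_reference=nearest,
            )
        )
    microbe_ids = refs + queries
    values = np.column_stack([columns[m] for m in microbe_ids])
    A = FunctionMicrobeMatrix(
        [str(f) for f in known_traits.columns], microbe_ids, values
    )
    return A, records


def collapse_identical(
    sequences: Mapping[str, str], traits: pd.DataFrame
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Collapse genomes with byte-identical 16S sequences into one cluster.

    The representative id is the lexicographically smallest member; its trait
    vector is the arithmetic mean over members, so
    ``cluster_size x representative`` preserves the members' trait totals.

    Returns (representative id -> sorted member ids, representative traits).
    """
    trait_index = set(str(i) for i in traits.index)
    missing = sorted(set(sequences) - trait_index)
    if missing:
        raise ValidationError(f"sequences without traits: {missing[:10]}")
    by_seq: dict[str, list[str]] = {}
    for gid in sorted(sequences):
        by_seq.setdefault(sequences[gid], []).append(gid)
    clusters = {min(members): sorted(members) for members in by_seq.values()}
    reps = sorted(clusters)
    rep_traits = pd.DataFrame(
        [traits.loc[clusters[rep]].mean(axis=0) for rep in reps],
        index=reps,
    )
    if len(reps) < len(sequences):
        logger.info(
            "collapsed %d genomes into %d clusters of identical 16S sequences",
            len(sequences), len(reps),
        )
    return clusters, rep_traits


def read_trait_table(path: Union[str, Path]) -> pd.DataFrame:
    """Genomes-as-rows trait table (same on-disk layout as a GCN table)."""
    from .io_formats import _read_numeric_frame

    return _read_numeric_frame(path, "trait table")


def write_trait_table(traits: pd.DataFrame, path: Union[str, Path]) -> None:
    from .io_formats import _write_table

    _write_table(
        path, "#genome ID",
        [str(i) for i in traits.index],
        [str(c) for c in traits.columns],
        traits.to_numpy(dtype=np.float64),
    )
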