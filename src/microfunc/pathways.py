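"""Roll KO-level profiles up to pathway level and normalize.

A KO mapping to several pathways contributes its full abundance to each of
them (the KEGG BRITE convention), so the pathway matrix deliberately over-
counts relative to the KO matrix; the mass-accounting identity that does
hold is: sum(pathway matrix) + sum(unmapped bucket) equals the multiplicity-
weighted sum of the KO profile.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import FunctionProfileMatrix, PathwayMap
from .errors import ValidationError

logger = logging.getLogger("microfunc")

__all__ = ["aggregate_to_pathways", "PathwayAggregation", "relative_abundance", "top_n_features"]


@dataclass
class PathwayAggregation:
    """Pathway x sample profile plus the unmapped-KO bucket."""

    profile: FunctionProfileMatrix  # rows are pathway ids
    unmapped_abundance: np.ndarray  # per-sample sum over KOs absent from the map
    unmapped_function_ids: list[str]


def aggregate_to_pathways(C: FunctionProfileMatrix, pmap: PathwayMap) -> PathwayAggregation:
    """Sum KO abundances into their pathways (full contribution to each).

    KOs absent from the map are collected in an ``unmapped`` bucket, reported
    but excluded from the pathway rows. Pathway rows are sorted by id.
    """
    if len(pmap) == 0:
        raise ValidationError("pathway map is empty")
    pathway_ids = pmap.pathway_ids
    index = {p: i for i, p in enumerate(pathway_ids)}
    values = np.zeros((len(pathway_ids), C.n_samples))
    unmapped = np.zeros(C.n_samples)
    unmapped_ids: list[str] = []
    for row, ko in zip(C.values, C.function_ids):
        pws = pmap.pathways_of(ko)
        if not pws:
            unmapped += row
            unmapped_ids.append(ko)
            continue
        for pw in pws:
            values[index[pw]] += row
    if unmapped_ids:
        logger.info(
            "%d function(s) absent from the pathway map went to the unmapped bucket",
            len(unmapped_ids),
        )
    profile = FunctionProfileMatrix(pathway_ids, list(C.sample_ids), values)
    return PathwayAggregation(profile, unmapped, unmapped_ids)


def relative_abundance(M):
    """Normalize each sample column to sum to 1; zero columns stay zero.

    Accepts any of the package's feature x sample containers or a bare array;
    returns the same kind.
    """
    values = np.asarray(M.values if hasattr(M, "values") else M, dtype=np.float64)
    if values.size and (values < 0).any():
        raise ValidationError("negative entries cannot be normalized to relative abundance")
    sums = values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("%d zero column(s) left as zero during normalization", int(zero.sum()))
    out = np.divide(values, np.where(zero, 1.0, sums), where=True)
    if hasattr(M, "values"):
        return type(M)(list(M.function_ids), list(M.sample_ids), out)
    return out


def top_n_features(M, n: int) -> list[str]:
    """Feature ids ranked by total abundance across samples, descending.

    Ties break toward the lexicographically smaller id. If ``n`` exceeds the
    number of features, all features are returned with a warning.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ids = list(M.function_ids)
    totals = np.asarray(M.values).sum(axis=1)
    if n > len(ids):
        logger.warning("requested top %d of only %d features; returning all", n, len(ids))
        n = len(ids)
    order = sorted(range(len(ids)), key=lambda i: (-totals[i], ids[i]))
    return [ids[i] for i in order[:n]]
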