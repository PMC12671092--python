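"""Per-sample weighted NSTI: an abundance-weighted confidence score.

The nearest sequenced taxon index of a microbe is its phylogenetic distance
to the closest sequenced reference genome. Averaging those distances over a
sample, weighted by microbe abundance, gives a single per-sample number:
small values mean the community is well covered by the reference database,
large values mean predictions lean on distant relatives.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .containers import AbundanceTable
from .errors import ValidationError
from .gcn import ReferenceRecord

logger = logging.getLogger("microfunc")

__all__ = ["weighted_nsti", "nsti_profile"]


def weighted_nsti(sample_abundances, distances) -> float:
    """Abundance-weighted mean of per-microbe NSTI distances.

    ``sum_k b_k * d_k / sum_k b_k`` — invariant to rescaling all abundances,
    and bounded by the min and max distance of microbes present (b_k > 0).
    """
    b = np.asarray(sample_abundances, dtype=np.float64)
    d = np.asarray(distances, dtype=np.float64)
    if b.shape != d.shape or b.ndim != 1:
        raise ValidationError("abundances and distances must be 1-D and equal length")
    if (b < 0).any():
        raise ValidationError("negative abundance")
    if not np.isfinite(d).all() or (d < 0).any():
        raise ValidationError("distances must be finite and non-negative")
    total = b.sum()
    if not total > 0:
        raise ValidationError("zero total abundance: weighted NSTI undefined")
    return float((b @ d) / total)


def _distance_lookup(
    records: Union[Mapping[str, float], Iterable[ReferenceRecord]],
) -> Mapping[str, float]:
    if isinstance(records, Mapping):
        return records
    return {r.microbe_id: r.nsti_distance for r in records}


def nsti_profile(
    B: AbundanceTable,
    records: Union[Mapping[str, float], Iterable[ReferenceRecord]],
) -> pd.Series:
    """Weighted NSTI per sample, aligned with ``B.sample_ids``.

    Samples with zero total abundance get NaN with a warning. A microbe that
    is present (non-zero abundance) anywhere but has no distance is an error.
    """
    lookup = _distance_lookup(records)
    present = np.flatnonzero(B.values.sum(axis=1) > 0)
    missing = [B.microbe_ids[k] for k in present if B.microbe_ids[k] not in lookup]
    if missing:
        raise ValidationError(
            f"no NSTI distance for present microbe(s): {missing[:10]}"
        )
    d = np.array([lookup.get(m, 0.0) for m in B.microbe_ids])
    totals = B.values.sum(axis=0)
    out = np.full(B.n_samples, np.nan)
    nonzero = totals > 0
    if not nonzero.all():
        empty = [s for s, nz in zip(B.sample_ids, nonzero) if not nz]
        logger.warning("samples with zero abundance reported as NaN: %s", empty[:10])
    out[nonzero] = (d @ B.values[:, nonzero]) / totals[nonzero]
    return pd.Series(out, index=pd.Index(B.sample_ids, name="sample"), name="weighted_nsti")
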