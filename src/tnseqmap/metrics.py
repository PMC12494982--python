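"""Per-feature and genome-wide insertion metrics: LD, RPKM, NE normalization.

LD (linear density) is the number of distinct inserted positions in a region
divided by its length in bp; by default repeated positions are excluded from
both numerator and denominator, since mapping ambiguity makes them
uninformative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .genome import AnnotationSet, Feature, RepeatMask
from .insertions import InsertionSample, MergedDataset

CountsLike = Union[InsertionSample, MergedDataset, Mapping[int, int]]


def _counts(data: CountsLike) -> Mapping[int, int]:
    if isinstance(data, (InsertionSample, MergedDataset)):
        return data.counts
    return data


@dataclass
class FeatureMetrics:
    feature_id: str
    length: int
    effective_length: int
    n_insertions: int
    total_reads: int
    ld: float  # NaN when effective_length == 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ld)


def linear_density(
    data: CountsLike,
    feature: Feature,
    mask: Optional[RepeatMask] = None,
    exclude_repeats: bool = True,
    position_weight: Optional[Callable[[int], float]] = None,
) -> FeatureMetrics:
    """Distinct inserted positions per effective bp of a feature.

    With ``exclude_repeats`` (default) repeated positions are removed from the
    numerator and the denominator counts only non-repeated bases. A fully
    repeated feature yields an NaN LD sentinel, never a silent zero.

    ``position_weight`` is a hook for sequence-composition corrections (e.g.
    insertion-site base preferences): when given, each inserted position
    contributes its weight to the LD numerator instead of 1. Off by default;
    no correction is applied.
    """
    counts = _counts(data)
    if exclude_repeats and mask is None:
        raise ValueError("exclude_repeats=True requires a repeat mask")
    positions = [p for p in counts if feature.start <= p <= feature.end]
    if exclude_repeats:
        flags = mask.flags
        positions = [p for p in positions if not flags[p - 1]]
        eff_len = feature.length - int(flags[feature.start - 1 : feature.end].sum())
    else:
        eff_len = feature.length
    if position_weight is None:
        n_ins = len(positions)
    else:
        n_ins = sum(position_weight(p) for p in positions)
    total = sum(counts[p] for p in positions)
    ld = n_ins / eff_len if eff_len > 0 else float("nan")
    return FeatureMetrics(
        feature_id=feature.id,
        length=feature.length,
        effective_length=eff_len,
        n_insertions=n_ins,
        total_reads=total,
        ld=ld,
    )


def genome_wide_ld(
    n_insertions: int, genome_length: int, as_percent: bool = False
) -> float:
    """Genome-wide LD: distinct insertions over total genome length.

    No repeat exclusion here — the genome-wide figure counts every position
    as a possible insertion site.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    ld = n_insertions / genome_length
    return 100.0 * ld if as_percent else ld


def rpkm(data: CountsLike, feature: Feature, library_total_reads: int) -> float:
    """Reads mapping an insertion in the feature per kb per million reads."""
    if library_total_reads <= 0:
        raise ValueError("library_total_reads must be positive")
    if feature.length <= 0:
        raise ValueError("zero-length feature")
    counts = _counts(data)
    reads = sum(r for p, r in counts.items() if feature.start <= p <= feature.end)
    return reads / (feature.length / 1e3) / (library_total_reads / 1e6)


def metrics_table(
    data: CountsLike,
    annot: AnnotationSet,
    mask: Optional[RepeatMask] = None,
    exclude_repeats: bool = True,
    library_total_reads: Optional[int] = None,
) -> pd.DataFrame:
    """Per-feature metric table (one row per feature).

    Vectorized equivalent of calling :func:`linear_density` and :func:`rpkm`
    per feature; positions are range-queried via binary search.
    """
    counts = _counts(data)
    if exclude_repeats and mask is None:
        raise ValueError("exclude_repeats=True requires a repeat mask")
    total = library_total_reads
    if total is None:
        total = sum(counts.values())

    pos = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
    reads = np.fromiter(counts.values(), dtype=np.int64, count=len(counts))
    order = np.argsort(pos)
    pos, reads = pos[order], reads[order]
    if exclude_repeats:
        flags = mask.flags
        ok = ~flags[pos - 1] if pos.size else np.zeros(0, dtype=bool)
        pos, reads = pos[ok], reads[ok]
        rep_cum = np.concatenate([[0], np.cumsum(flags)])
    reads_cum = np.concatenate([[0], np.cumsum(reads)])

    rows = []
    for f in annot:
        lo = np.searchsorted(pos, f.start, side="left")
        hi = np.searchsorted(pos, f.end, side="right")
        n_ins = int(hi - lo)
        f_reads = int(reads_cum[hi] - reads_cum[lo])
        if exclude_repeats:
            eff = f.length - int(rep_cum[f.end] - rep_cum[f.start - 1])
        else:
            eff = f.length
        ld = n_ins / eff if eff > 0 else float("nan")
        rows.append(
            {
                "feature_id": f.id,
                "ftype": f.ftype,
                "length": f.length,
                "effective_length": eff,
                "n_insertions": n_ins,
                "total_reads": f_reads,
                "ld": ld,
                "rpkm": (
                    f_reads / (f.length / 1e3) / (total / 1e6) if total > 0 else 0.0
                ),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def ne_normalize(
    values: Mapping[str, float] | pd.Series, gold_ne: set[str]
) -> pd.Series:
    """Divide each feature's value by the mean value of the gold-NE set.

    Normalized values are >= 0 and may exceed 1 when a feature out-inserts
    the NE reference in the same sample.
    """
    series = pd.Series(values, dtype=float)
    gold = series.reindex(sorted(gold_ne)).dropna()
    if gold.empty:
        raise ValueError("gold-NE set is empty or has no defined values")
    denom = gold.mean()
    if denom == 0:
        raise ValueError("gold-NE mean is zero; cannot normalize")
    return series / denom
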