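"""Annotation-independent E/NE genome segmentation via a sliding window.

Step-1 windows of a calibrated size (default 31 bp) are scored by linear
density on their non-repeated bases, classified E/NE by an unsupervised
two-component mixture, and bases covered by any NE window become NE domains;
everything else is E. Windows with no non-repeated base are uninformative
and do not vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotationSet, Genome, RepeatMask
from .gmm import fit_mixture, classify_binary
from .metrics import _counts


@dataclass
class WindowTrack:
    w: int
    step: int
    starts: np.ndarray  # 1-based window start positions
    ld: np.ndarray  # per-window LD on non-repeated bases (NaN if uninformative)
    informative: np.ndarray  # bool

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.w // 2


@dataclass
class Segment:
    start: int
    end: int
    label: str  # "E" | "NE"
    pct_repeated: float = 0.0
    reported: bool = True
    auc: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _position_array(data, genome_length: int) -> np.ndarray:
    ins = np.zeros(genome_length, dtype=np.float64)
    for p in _counts(data):
        if 1 <= p <= genome_length:
            ins[p - 1] = 1.0
    return ins


def window_track(
    data,
    genome_length: int,
    mask: Optional[RepeatMask] = None,
    w: int = 31,
    step: int = 1,
) -> WindowTrack:
    """Per-window LD over non-repeated bases, computed by cumulative sums."""
    if w > genome_length:
        raise ValueError(f"window w={w} exceeds genome length {genome_length}")
    ins = _position_array(data, genome_length)
    if mask is not None:
        rep = mask.flags.astype(np.float64)
        ins = ins * (1.0 - rep)
        ok = 1.0 - rep
    else:
        ok = np.ones(genome_length)
    cs_ins = np.concatenate([[0.0], np.cumsum(ins)])
    cs_ok = np.concatenate([[0.0], np.cumsum(ok)])
    starts = np.arange(1, genome_length - w + 2, step)
    i0 = starts - 1
    n_ins = cs_ins[i0 + w] - cs_ins[i0]
    n_ok = cs_ok[i0 + w] - cs_ok[i0]
    informative = n_ok > 0
    ld = np.full(starts.shape, np.nan)
    ld[informative] = n_ins[informative] / n_ok[informative]
    return WindowTrack(w=w, step=step, starts=starts, ld=ld, informative=informative)


def _binary_window_calls(lds: np.ndarray, seed: int) -> np.ndarray:
    """Classify window LDs as NE (True) / E (False) with a 2-component GMM.

    Degenerate inputs (effectively constant LD) fall back to a global call:
    all NE when the common density is closer to saturation than to zero.
    """
    vals = lds[~np.isnan(lds)]
    if vals.size == 0:
        return np.zeros(lds.shape, dtype=bool)
    sel = fit_mixture(vals, k_candidates=[2], seed=seed) if np.ptp(vals) > 1e-9 else None
    if sel is None or sel.fits.get(2) is None or sel.fits[2].degenerate:
        return ~np.isnan(lds) & (lds > 0.5)
    fit = sel.fits[2]
    if abs(fit.means[0] - fit.means[1]) < 1e-6:
        return ~np.isnan(lds) & (lds > 0.5)
    # unimodal guards: when both components sit on the same side of the E/NE
    # divide, the data carry no essential/non-essential contrast
    if fit.means.min() > 0.5:
        return ~np.isnan(lds)
    if fit.means.max() < 0.05:
        return np.zeros(lds.shape, dtype=bool)
    values = {i: v for i, v in enumerate(lds) if not np.isnan(v)}
    calls = classify_binary(values, fit)
    ne = np.zeros(lds.shape, dtype=bool)
    for c in calls:
        if c.category == "NE":
            ne[c.feature_id] = True
    return ne


def segment_genome(
    data,
    genome: Genome,
    mask: Optional[RepeatMask] = None,
    w: int = 31,
    seed: int = 0,
    coverage_rule: str = "any",
) -> list[Segment]:
    """Tile the genome into alternating E/NE segments.

    A base is NE when at least one informative covering window is classified
    NE (``coverage_rule="any"``; ``"majority"`` requires more NE than E
    covering windows). Remaining bases, including fully repeated stretches,
    are E. Adjacent same-label bases merge into maximal segments that
    partition the genome exactly.
    """
    if coverage_rule not in ("any", "majority"):
        raise ValueError(f"unknown coverage rule {coverage_rule!r}")
    n = genome.length
    track = window_track(data, n, mask=mask, w=w)
    ne_calls = _binary_window_calls(track.ld, seed)

    ne_votes = np.zeros(n + 1)
    e_votes = np.zeros(n + 1)
    for start, is_ne, inf in zip(track.starts, ne_calls, track.informative):
        if not inf:
            continue
        tgt = ne_votes if is_ne else e_votes
        tgt[start - 1] += 1
        tgt[start - 1 + w] -= 1
    ne_cov = np.cumsum(ne_votes[:-1])
    e_cov = np.cumsum(e_votes[:-1])
    if coverage_rule == "any":
        is_ne = ne_cov > 0
    else:
        is_ne = ne_cov > e_cov

    segments = []
    i = 0
    while i < n:
        j = i
        while j < n and is_ne[j] == is_ne[i]:
            j += 1
        label = "NE" if is_ne[i] else "E"
        seg = Segment(start=i + 1, end=j, label=label)
        if mask is not None:
            seg.pct_repeated = float(mask.flags[i:j].mean())
        segments.append(seg)
        i = j
    return segments


def filter_segments(
    segments: Sequence[Segment], min_len: int = 5, max_repeat: float = 0.10
) -> list[Segment]:
    """Mark E segments failing the length / repeat criteria as unreported.

    The genome tiling is preserved: segments are returned in place with the
    ``reported`` flag cleared rather than removed.
    """
    for s in segments:
        if s.label == "E" and (s.length < min_len or s.pct_repeated >= max_repeat):
            s.reported = False
        else:
            s.reported = True
    return list(segments)


def map_segments(
    segments: Sequence[Segment], annot: AnnotationSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap bookkeeping between segments and annotation.

    Returns (per-feature table, per-segment table). Per feature: fraction of
    its length covered by E segments and the number of distinct E segments
    touched. Per segment: overlapping feature ids, or "non-annotated".
    """
    feat_rows = []
    for f in annot:
        e_bp = 0
        n_e = 0
        for s in segments:
            if s.label != "E":
                continue
            ov = min(s.end, f.end) - max(s.start, f.start) + 1
            if ov > 0:
                e_bp += ov
                n_e += 1
        feat_rows.append(
            {
                "feature_id": f.id,
                "ftype": f.ftype,
                "pct_essential": e_bp / f.length,
                "n_e_segments": n_e,
            }
        )
    seg_rows = []
    for idx, s in enumerate(segments):
        hits = [f.id for f in annot.overlapping(s.start, s.end)]
        seg_rows.append(
            {
                "segment": idx,
                "start": s.start,
                "end": s.end,
                "label": s.label,
                "reported": s.reported,
                "features": ",".join(hits) if hits else "non-annotated",
            }
        )
    return (
        pd.DataFrame(feat_rows).set_index("feature_id"),
        pd.DataFrame(seg_rows).set_index("segment"),
    )


@dataclass
class CalibrationResult:
    sizes: np.ndarray
    error: np.ndarray  # P(E window called NE) per size
    chosen_w: Optional[int]
    tolerance: float


def sample_window_pools(
    data,
    genes: Sequence,
    genome_length: int,
    w: int,
    n_windows: int,
    rng: np.random.Generator,
    mask: Optional[RepeatMask] = None,
) -> np.ndarray:
    """LDs of ``n_windows`` windows of size ``w`` sampled inside the genes."""
    ins = _position_array(data, genome_length)
    if mask is not None:
        ok = 1.0 - mask.flags.astype(float)
        ins = ins * ok
    else:
        ok = np.ones(genome_length)
    cs_ins = np.concatenate([[0.0], np.cumsum(ins)])
    cs_ok = np.concatenate([[0.0], np.cumsum(ok)])
    eligible = [g for g in genes if g.length >= w]
    if not eligible:
        raise ValueError(f"no gene long enough for window size {w}")
    lds = np.empty(n_windows)
    gi = rng.integers(0, len(eligible), size=n_windows)
    for i in range(n_windows):
        g = eligible[gi[i]]
        start = int(rng.integers(g.start, g.end - w + 2))
        i0 = start - 1
        denom = cs_ok[i0 + w] - cs_ok[i0]
        lds[i] = (cs_ins[i0 + w] - cs_ins[i0]) / denom if denom > 0 else np.nan
    return lds[~np.isnan(lds)]


def calibrate_window(
    data,
    e_genes: Sequence,
    ne_genes: Sequence,
    genome_length: int,
    sizes: Sequence[int] = range(3, 151),
    n_windows: int = 500,
    tolerance: float = 0.05,
    seed: int = 0,
    mask: Optional[RepeatMask] = None,
) -> CalibrationResult:
    """Choose the smallest window size whose E->NE misclassification rate is
    below ``tolerance``.

    For each size, pools of windows are sampled from genes of known E and NE
    essentiality, a two-component mixture is fit on the pooled window LDs,
    windows are classified, and the fraction of E-gene windows called NE is
    recorded.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(sorted(sizes))
    errors = np.empty(len(sizes))
    for si, w in enumerate(sizes):
        e_pool = sample_window_pools(data, e_genes, genome_length, int(w), n_windows, rng, mask)
        ne_pool = sample_window_pools(data, ne_genes, genome_length, int(w), n_windows, rng, mask)
        if e_pool.size < 10 or ne_pool.size < 10:
            raise ValueError(f"window pools too small at size {w}")
        pooled = np.concatenate([e_pool, ne_pool])
        ne_flags = _binary_window_calls(pooled, seed)
        errors[si] = float(ne_flags[: e_pool.size].mean())
    admissible = np.nonzero(errors < tolerance)[0]
    chosen = int(sizes[admissible[0]]) if admissible.size else None
    return CalibrationResult(sizes=sizes, error=errors, chosen_w=chosen,
                             tolerance=tolerance)


def segments_to_bed(segments: Sequence[Segment], genome_id: str, path) -> None:
    """BED export (0-based half-open) of reported segments."""
    with open(path, "w") as fh:
        for s in segments:
            if not s.reported:
                continue
            fh.write(f"{genome_id}\t{s.start - 1}\t{s.end}\t{s.label}\n")
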