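"""NE-normalized decay trajectories, k-means clustering, and trapezoidal AUC.

The AUC over a feature's NE-normalized trajectory is the quantitative
essentiality score: a persistent (non-essential) feature keeps values near 1
across passages and accrues a large area; a costly disruption decays fast
and accrues little.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genome import Feature
from .metrics import ne_normalize

GENE_AUC_PASSAGES = (1, 2, 3, 4, 6, 8, 10)
SEGMENT_AUC_PASSAGES = (1, 2, 3, 4, 5, 6, 7, 8)


@dataclass
class DecayProfile:
    feature_id: str
    passages: tuple[int, ...]
    values: np.ndarray  # NE-normalized metric per passage
    cluster: Optional[int] = None
    auc: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.passages) != len(self.values):
            raise ValueError("passages and values must align")
        if len(self.passages) < 2:
            raise ValueError("a decay profile needs at least 2 passages")


@dataclass
class LibraryComparison:
    element_id: str
    auc_p: np.ndarray
    auc_t: np.ndarray
    fold_change: float
    p_value: float
    verdict: str  # "P-enriched" | "T-enriched" | "n.s."


def build_trajectories(
    ld_by_passage: dict[int, dict[str, float]],
    gold_ne: set[str],
    feature_ids: Optional[Sequence[str]] = None,
) -> list[DecayProfile]:
    """NE-normalize per-passage LD maps and assemble per-feature trajectories.

    ``ld_by_passage`` maps passage -> {feature_id -> LD}. Each passage is
    normalized by its own gold-NE mean, so trajectories are comparable across
    sequencing depths. Features present in fewer than 2 passages are skipped.
    Missing passages are omitted from a feature's grid, never imputed.
    """
    passages = sorted(ld_by_passage)
    if len(passages) < 2:
        raise ValueError("need at least 2 passages")
    normalized = {p: ne_normalize(ld_by_passage[p], gold_ne) for p in passages}
    if feature_ids is None:
        ids = sorted(set().union(*(set(ld_by_passage[p]) for p in passages)))
    else:
        ids = list(feature_ids)
    profiles = []
    for fid in ids:
        grid, vals = [], []
        for p in passages:
            v = normalized[p].get(fid, np.nan)
            if not np.isnan(v):
                grid.append(p)
                vals.append(v)
        if len(grid) < 2:
            continue
        profiles.append(DecayProfile(fid, tuple(grid), np.array(vals)))
    return profiles


def auc(profile: DecayProfile, passage_range: Sequence[int] = GENE_AUC_PASSAGES) -> float:
    """Trapezoidal area under the trajectory restricted to ``passage_range``."""
    grid = [i for i, p in enumerate(profile.passages) if p in set(passage_range)]
    if len(grid) < 2:
        raise ValueError(
            f"{profile.feature_id}: fewer than 2 points within the passage range"
        )
    x = np.array([profile.passages[i] for i in grid], dtype=float)
    y = profile.values[grid]
    return float(np.trapezoid(y, x))


def assign_auc(
    profiles: Sequence[DecayProfile], passage_range: Sequence[int] = GENE_AUC_PASSAGES
) -> None:
    for pr in profiles:
        pr.auc = auc(pr, passage_range)


@dataclass
class KMeansResult:
    profiles: list[DecayProfile]  # clustered (cluster labels set)
    excluded: list[str]  # feature ids dropped before clustering
    k: int
    distortion: pd.DataFrame  # k, distortion


def _common_grid_matrix(profiles: Sequence[DecayProfile]):
    grids = {pr.passages for pr in profiles}
    full = max(grids, key=len)
    usable = [pr for pr in profiles if pr.passages == full]
    dropped = [pr.feature_id for pr in profiles if pr.passages != full]
    X = np.vstack([pr.values for pr in usable]) if usable else np.empty((0, len(full)))
    return usable, dropped, X


def kmeans_decay(
    profiles: Sequence[DecayProfile],
    k: Optional[int] = None,
    k_candidates: Sequence[int] = range(1, 9),
    pct_repeated: Optional[dict[str, float]] = None,
    max_repeat: float = 0.25,
    min_cluster_size: int = 50,
    seed: int = 0,
    elbow_drop: float = 0.5,
    passage_range: Sequence[int] = GENE_AUC_PASSAGES,
) -> KMeansResult:
    """Cluster decay trajectories by k-means with elbow selection.

    High-repeat features (``pct_repeated`` above ``max_repeat``) are excluded
    before clustering since inflated LDs on their few mappable positions
    distort trajectory shapes. Candidate k values whose smallest cluster
    falls below ``min_cluster_size`` are rejected. The elbow is the candidate
    with the largest relative distortion drop; an explicit ``k`` overrides
    selection. Cluster labels are re-ordered by ascending mean AUC so label 0
    is always the most essential cluster.
    """
    excluded = []
    kept = []
    for pr in profiles:
        if pct_repeated is not None and pct_repeated.get(pr.feature_id, 0.0) > max_repeat:
            excluded.append(pr.feature_id)
        else:
            kept.append(pr)
    usable, dropped_grid, X = _common_grid_matrix(kept)
    excluded.extend(dropped_grid)
    n = len(usable)
    if n == 0:
        raise ValueError("no profiles left to cluster")

    candidates = [c for c in sorted(k_candidates) if c <= n]
    if not candidates:
        raise ValueError("fewer profiles than any candidate k")

    models = {}
    rows = []
    for c in candidates:
        km = KMeans(n_clusters=c, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        sizes = np.bincount(labels, minlength=c)
        admissible = c == 1 or sizes.min() >= min_cluster_size
        models[c] = (km, labels, admissible)
        rows.append({"k": c, "distortion": float(km.inertia_), "admissible": admissible})
    dist = pd.DataFrame(rows)

    if k is None:
        admissible = [c for c in candidates if models[c][2]]
        if not admissible:
            admissible = [candidates[0]]
        if len(admissible) == 1:
            k_sel = admissible[0]
        else:
            # elbow: advance while each extra cluster still cuts distortion
            # by at least ``elbow_drop``; stop where the curve flattens
            d = {c: models[c][0].inertia_ for c in admissible}
            k_sel = admissible[0]
            for a, b in zip(admissible, admissible[1:]):
                rel = (d[a] - d[b]) / d[a] if d[a] > 0 else 0.0
                if rel >= elbow_drop:
                    k_sel = b
                else:
                    break
    else:
        if k > n:
            raise ValueError(f"k={k} exceeds the number of profiles ({n})")
        if k not in models:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            models[k] = (km, km.fit_predict(X), True)
        k_sel = k

    _, labels, _ = models[k_sel]
    for pr in usable:
        if pr.auc is None:
            pr.auc = auc(pr, passage_range)
    # deterministic labels: re-ordered by ascending mean AUC
    mean_auc = {}
    for lab in range(k_sel):
        members = [pr.auc for pr, l in zip(usable, labels) if l == lab]
        mean_auc[lab] = float(np.mean(members)) if members else np.inf
    order = sorted(range(k_sel), key=lambda l: mean_auc[l])
    relabel = {old: new for new, old in enumerate(order)}
    for pr, lab in zip(usable, labels):
        pr.cluster = relabel[int(lab)]
    return KMeansResult(profiles=list(usable), excluded=excluded, k=k_sel, distortion=dist)


def compare_libraries_auc(
    profiles_p: dict[str, Sequence[DecayProfile]],
    profiles_t: dict[str, Sequence[DecayProfile]],
    alpha: float = 0.05,
    passage_range: Sequence[int] = GENE_AUC_PASSAGES,
    paired: bool = False,
) -> list[LibraryComparison]:
    """Per-element one-tailed t-test of replicate AUCs between P and T.

    ``profiles_p``/``profiles_t`` map element id -> per-replicate profiles.
    The test direction follows the observed fold-change (mean P over mean T);
    significance is declared at ``alpha``. Zero-variance exact ties are n.s.
    """
    out = []
    for eid in sorted(set(profiles_p) & set(profiles_t)):
        ap = np.array([auc(pr, passage_range) for pr in profiles_p[eid]])
        at = np.array([auc(pr, passage_range) for pr in profiles_t[eid]])
        if len(ap) < 2 or len(at) < 2:
            continue
        mp, mt = ap.mean(), at.mean()
        fc = mp / mt if mt > 0 else np.inf
        if np.allclose(ap, at) or (ap.std() == 0 and at.std() == 0 and mp == mt):
            out.append(LibraryComparison(eid, ap, at, 1.0, 1.0, "n.s."))
            continue
        alternative = "greater" if mp >= mt else "less"
        if paired:
            res = stats.ttest_rel(ap, at, alternative=alternative)
        else:
            res = stats.ttest_ind(ap, at, alternative=alternative)
        p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0
        if p < alpha:
            verdict = "P-enriched" if mp > mt else "T-enriched"
        else:
            verdict = "n.s."
        out.append(LibraryComparison(eid, ap, at, float(fc), p, verdict))
    return out


@dataclass
class TerminiResult:
    gene_id: str
    n_extension_aa: int
    c_extension_aa: int
    auc_gene: Optional[float] = None
    auc_n_terminus: Optional[float] = None
    auc_c_terminus: Optional[float] = None
    ratio_n: Optional[float] = None
    ratio_c: Optional[float] = None


def termini_analysis(
    genes: Sequence[Feature],
    segments,
    gene_profiles: Optional[dict[str, DecayProfile]] = None,
    terminus_profiles: Optional[dict[str, tuple[DecayProfile, DecayProfile]]] = None,
    passage_range: Sequence[int] = GENE_AUC_PASSAGES,
) -> list[TerminiResult]:
    """Per-gene N/C NE-extension lengths (aa) from NE segments, plus AUC ratios.

    The N-terminal extension is the overlap between the gene's 5' end and an
    NE segment covering that end (strand-aware); likewise for the C terminus.
    Extensions are floor(bp / 3) amino acids. When per-gene and per-terminus
    decay profiles are supplied, the terminus-to-gene AUC ratio is reported,
    guarded against undefined division.
    """
    ne_segments = [s for s in segments if s.label == "NE"]
    out = []
    for g in genes:
        left = 0
        right = 0
        for s in ne_segments:
            if s.start <= g.start <= s.end:
                left = min(s.end, g.end) - g.start + 1
            if s.start <= g.end <= s.end:
                right = g.end - max(s.start, g.start) + 1
        if g.strand == "-":
            n_bp, c_bp = right, left
        else:
            n_bp, c_bp = left, right
        res = TerminiResult(g.id, n_bp // 3, c_bp // 3)
        if gene_profiles and g.id in gene_profiles:
            res.auc_gene = auc(gene_profiles[g.id], passage_range)
        if terminus_profiles and g.id in terminus_profiles:
            npr, cpr = terminus_profiles[g.id]
            res.auc_n_terminus = auc(npr, passage_range)
            res.auc_c_terminus = auc(cpr, passage_range)
            if res.auc_gene and res.auc_gene > 0:
                res.ratio_n = res.auc_n_terminus / res.auc_gene
                res.ratio_c = res.auc_c_terminus / res.auc_gene
        out.append(res)
    return out


def profiles_table(profiles: Sequence[DecayProfile]) -> pd.DataFrame:
    rows = []
    for pr in profiles:
        row = {"feature_id": pr.feature_id, "cluster": pr.cluster, "auc": pr.auc}
        row.update({f"p{p}": v for p, v in zip(pr.passages, pr.values)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature_id")
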