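"""Insertion-enrichment statistics over serial passages.

Identifies insertion positions positively selected between the first and
last passage (TMM-normalized counts, one-tailed t-test, Bonferroni),
categorizes them against the annotation, and runs COG hypergeometric and
binding-site accessibility statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import AnnotationSet, Feature, RepeatMask, upstream_interval
from .insertions import InsertionSample
from .metrics import _counts

POSITION_CATEGORIES = (
    "overlap E/F1 gene",
    "overlap F2/NE gene",
    "upstream E/F1 gene",
    "upstream F2/NE gene",
    "overlap UTR5",
    "upstream UTR5",
    "overlap iGiO",
    "overlap non-transcribed",
    "between two gene ends",
    "not classified",
)


@dataclass
class EnrichedPosition:
    position: int
    library: str
    log2fc: float
    p_raw: float
    p_adj: float
    enriched: bool
    categories: tuple[str, ...] = ("not classified",)


@dataclass
class CogEnrichment:
    cog: str
    n_hit: int
    n_category: int
    n_background: int
    n_hit_total: int
    p_hyper: float
    q_bh: float = float("nan")


def valid_positions(
    p1_rep1: InsertionSample,
    p1_rep2: InsertionSample,
    p10_rep1: InsertionSample,
    p10_rep2: InsertionSample,
) -> set[int]:
    """Positions conserved in the first and last passage in both replicates."""
    sets = [s.positions for s in (p1_rep1, p1_rep2, p10_rep1, p10_rep2)]
    if any(not s for s in sets):
        return set()
    return set.intersection(*sets)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: Optional[str] = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = False,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors per sample column.

    Counts are positions x samples. For each sample, log2 ratios (M) and
    average abundances (A) against the reference are computed on co-detected
    positions; the most extreme ``trim_m`` of M and ``trim_a`` of A are
    trimmed symmetrically, and the factor is 2 to the mean of the surviving M
    values. With ``weighted=True`` the mean uses inverse asymptotic-variance
    precision weights; the unweighted default keeps factors exactly
    scale-equivariant under count rescaling. A normalized count is
    ``count / (library_size * factor)``.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if ref_sample is None:
        ref_sample = counts.columns[0]
    lib = counts.sum(axis=0).astype(float)
    ref = counts[ref_sample].to_numpy(dtype=float)
    n_ref = lib[ref_sample]
    factors = {}
    for col in counts.columns:
        if col == ref_sample:
            factors[col] = 1.0
            continue
        obs = counts[col].to_numpy(dtype=float)
        n_obs = lib[col]
        use = (obs > 0) & (ref > 0)
        if not use.any():
            raise ValueError(f"no co-detected positions between {col} and {ref_sample}")
        o, r = obs[use], ref[use]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        if m.size == 1:
            factors[col] = float(2.0 ** m[0])
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones(m.shape, dtype=bool)
        if weighted:
            with np.errstate(divide="ignore"):
                inv_w = 1.0 / w[keep]
            factors[col] = float(2.0 ** (np.sum(m[keep] * inv_w) / np.sum(inv_w)))
        else:
            factors[col] = float(2.0 ** m[keep].mean())
    return pd.Series(factors, name="tmm_factor")


def tmm_normalize(counts: pd.DataFrame, ref_sample: Optional[str] = None) -> pd.DataFrame:
    """Counts scaled by library size times TMM factor (reference scale)."""
    factors = tmm_factors(counts, ref_sample=ref_sample)
    lib = counts.sum(axis=0).astype(float)
    scale = lib * factors
    return counts / scale * scale.iloc[0]


def position_enrichment(
    valid: set[int],
    norm_p1: pd.DataFrame,
    norm_p10: pd.DataFrame,
    library: str = "P",
    alpha: float = 0.05,
    paired: bool = False,
) -> list[EnrichedPosition]:
    """Per-position one-tailed test for read gain between first/last passage.

    ``norm_p1``/``norm_p10`` are positions x replicates normalized counts.
    The alternative is fixed a priori to "passage 10 greater" (positive
    selection). Bonferroni correction runs over the positions actually
    tested; positions with zero passage-1 mean cannot form a ratio and are
    excluded, reported with NaN statistics.
    """
    tested: list[EnrichedPosition] = []
    skipped: list[EnrichedPosition] = []
    for pos in sorted(valid):
        if pos not in norm_p1.index or pos not in norm_p10.index:
            continue
        x1 = norm_p1.loc[pos].to_numpy(dtype=float)
        x10 = norm_p10.loc[pos].to_numpy(dtype=float)
        m1, m10 = x1.mean(), x10.mean()
        if m1 == 0:
            skipped.append(
                EnrichedPosition(pos, library, float("nan"), float("nan"),
                                 float("nan"), False)
            )
            continue
        log2fc = float(np.log2(m10 / m1)) if m10 > 0 else -np.inf
        if paired:
            res = stats.ttest_rel(x10, x1, alternative="greater")
        else:
            res = stats.ttest_ind(x10, x1, equal_var=False, alternative="greater")
        p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0
        tested.append(EnrichedPosition(pos, library, log2fc, p, 1.0, False))
    m = len(tested)
    for ep in tested:
        ep.p_adj = min(1.0, ep.p_raw * m)
        ep.enriched = ep.p_adj < alpha and ep.log2fc > 0
    return tested + skipped


def categorize_positions(
    positions: Sequence[int],
    annot: AnnotationSet,
    gene_categories: dict[str, str],
    upstream_window: int = 250,
    genome_length: Optional[int] = None,
) -> dict[int, tuple[str, ...]]:
    """Assign each position to all matching annotation categories.

    ``gene_categories`` maps gene id -> {E,F1,F2,NE}. "Upstream" is
    strand-aware within ``upstream_window`` bp of a gene start codon.
    Positions matching nothing fall back to "not classified".
    """
    if genome_length is None:
        genome_length = max((f.end for f in annot), default=0) + upstream_window
    genes = annot.genes
    utr5 = annot.of_type("UTR5")
    igio = annot.of_type("iGiO")
    noexp = annot.of_type("noexp", "noann")
    out = {}
    for pos in positions:
        cats = set()
        for g in genes:
            gc = gene_categories.get(g.id)
            ess = gc in ("E", "F1")
            if g.start <= pos <= g.end:
                cats.add("overlap E/F1 gene" if ess else "overlap F2/NE gene")
            else:
                us, ue = upstream_interval(g, upstream_window, genome_length)
                if us <= pos <= ue:
                    cats.add("upstream E/F1 gene" if ess else "upstream F2/NE gene")
        for u in utr5:
            if u.start <= pos <= u.end:
                cats.add("overlap UTR5")
            else:
                us, ue = upstream_interval(u, upstream_window, genome_length)
                if us <= pos <= ue:
                    cats.add("upstream UTR5")
        if any(f.start <= pos <= f.end for f in igio):
            cats.add("overlap iGiO")
        if any(f.start <= pos <= f.end for f in noexp):
            cats.add("overlap non-transcribed")
        # between the ends of two consecutive genes, inside neither
        ordered = sorted(genes, key=lambda g: g.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end < pos < b.start:
                cats.add("between two gene ends")
                break
        if not cats:
            cats.add("not classified")
        out[pos] = tuple(sorted(cats, key=POSITION_CATEGORIES.index))
    return out


def whole_gene_enrichment(
    gene: Feature,
    p1: InsertionSample | pd.Series,
    p10: InsertionSample | pd.Series,
    top_k_subtract: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Coding-sequence-wide read enrichment robust to a few hot insertions.

    The ``top_k_subtract`` insertions with the highest passage-10 reads are
    removed, then per-insertion reads at P10 vs P1 (shared positions) are
    compared by a one-tailed t-test. Genes with too few insertions are not
    evaluable.
    """
    c1 = dict(_counts(p1)) if not isinstance(p1, pd.Series) else p1.to_dict()
    c10 = dict(_counts(p10)) if not isinstance(p10, pd.Series) else p10.to_dict()
    in_gene10 = {p: r for p, r in c10.items() if gene.start <= p <= gene.end}
    if len(in_gene10) < top_k_subtract + 2:
        return {"gene_id": gene.id, "evaluable": False, "enriched": False,
                "p_value": float("nan")}
    hot = sorted(in_gene10, key=lambda p: (-in_gene10[p], p))[:top_k_subtract]
    keep = [p for p in in_gene10 if p not in hot and p in c1]
    if len(keep) < 2:
        return {"gene_id": gene.id, "evaluable": False, "enriched": False,
                "p_value": float("nan")}
    x1 = np.array([c1[p] for p in keep], dtype=float)
    x10 = np.array([in_gene10[p] for p in keep], dtype=float)
    if np.allclose(x1, x10):
        return {"gene_id": gene.id, "evaluable": True, "enriched": False,
                "p_value": 1.0}
    res = stats.ttest_rel(x10, x1, alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return {"gene_id": gene.id, "evaluable": True, "enriched": p < alpha,
            "p_value": p, "subtracted": hot}


def cog_enrichment(
    hit_genes: set[str], background: dict[str, str], alpha: float = 0.05
) -> list[CogEnrichment]:
    """Upper-tail hypergeometric COG enrichment with BH adjustment.

    ``background`` maps gene id -> COG letter for the full universe;
    ``hit_genes`` is the subset affected by an enriched insertion.
    """
    if not background:
        raise ValueError("empty background")
    unknown = hit_genes - set(background)
    if unknown:
        raise ValueError(f"hit genes absent from background: {sorted(unknown)[:5]}")
    m_total = len(background)
    n_hits = len(hit_genes)
    results = []
    for cog in sorted({c for c in background.values()}):
        members = {g for g, c in background.items() if c == cog}
        k = len(members & hit_genes)
        # P(X >= k) for X ~ Hypergeom(M=m_total, n=|members|, N=n_hits)
        p = float(stats.hypergeom.sf(k - 1, m_total, len(members), n_hits))
        results.append(
            CogEnrichment(cog=cog, n_hit=k, n_category=len(members),
                          n_background=m_total, n_hit_total=n_hits, p_hyper=min(p, 1.0))
        )
    if results:
        qs = multipletests([r.p_hyper for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_bh = float(q)
    return results


@dataclass
class AccessibilityResult:
    per_site: pd.DataFrame
    p_ld: float  # one-tailed paired t-test: site LD < mean flank LD
    p_reads: float
    n_sites: int


def accessibility_test(
    sites: Sequence[Feature],
    data,
    mask: Optional[RepeatMask] = None,
    genome_length: Optional[int] = None,
) -> AccessibilityResult:
    """Compare each binding site with equal-length upstream/downstream flanks.

    Per site, LD and total reads are computed for the site and its two
    flanks; across sites a one-tailed paired t-test asks whether the site
    value is lower than the mean of its flanks (insertion depletion under a
    bound protein). Sites whose flanks fall off the genome are skipped.
    """
    counts = _counts(data)
    if genome_length is None:
        genome_length = max(counts, default=0)
    rows = []
    for s in sites:
        L = s.length
        if s.start - L < 1 or s.end + L > genome_length:
            continue

        def _metrics(a: int, b: int) -> tuple[float, int]:
            pos = [p for p in counts if a <= p <= b]
            if mask is not None:
                pos = [p for p in pos if not mask.flags[p - 1]]
                eff = (b - a + 1) - int(mask.flags[a - 1 : b].sum())
            else:
                eff = b - a + 1
            ld = len(pos) / eff if eff else float("nan")
            return ld, sum(counts[p] for p in pos)

        site_ld, site_reads = _metrics(s.start, s.end)
        up_ld, up_reads = _metrics(s.start - L, s.start - 1)
        dn_ld, dn_reads = _metrics(s.end + 1, s.end + L)
        rows.append(
            {
                "site_id": s.id,
                "site_ld": site_ld,
                "flank_ld": (up_ld + dn_ld) / 2,
                "site_reads": site_reads,
                "flank_reads": (up_reads + dn_reads) / 2,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        res_ld = stats.ttest_rel(df["site_ld"], df["flank_ld"], alternative="less")
        res_rd = stats.ttest_rel(df["site_reads"], df["flank_reads"], alternative="less")
        p_ld, p_rd = float(res_ld.pvalue), float(res_rd.pvalue)
        if np.isnan(p_ld):
            p_ld = 1.0
        if np.isnan(p_rd):
            p_rd = 1.0
    else:
        p_ld = p_rd = float("nan")
    return AccessibilityResult(per_site=df, p_ld=p_ld, p_reads=p_rd, n_sites=len(df))


def enriched_table(positions: Sequence[EnrichedPosition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [e.position for e in positions],
            "library": [e.library for e in positions],
            "log2fc": [e.log2fc for e in positions],
            "p_raw": [e.p_raw for e in positions],
            "p_adj": [e.p_adj for e in positions],
            "enriched": [e.enriched for e in positions],
            "categories": [";".join(e.categories) for e in positions],
        }
    ).set_index("position")
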