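"""Unsupervised essentiality classification of LD values by Gaussian mixtures.

Components are mapped to essentiality categories by ascending mean: the
lowest-mean component is E, the highest NE. In 4-component mode the two
middle components are F1 (quasi-essential) and F2 (quasi-non-essential); in
2-component mode only E and NE are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .genome import AnnotationSet, Feature

CATEGORIES_4 = ("E", "F1", "F2", "NE")
CATEGORIES_2 = ("E", "NE")


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    aic: float
    bic: float
    seed: int
    converged: bool
    degenerate: bool = False
    _model: Optional[GaussianMixture] = field(default=None, repr=False)

    @property
    def order(self) -> np.ndarray:
        """Component indices sorted by ascending mean."""
        return np.argsort(self.means)


@dataclass
class EssentialityCall:
    feature_id: str
    ld: float
    category: str
    posteriors: dict[str, float]


@dataclass
class MixtureSelection:
    fits: dict[int, MixtureFit]
    selected_k: int
    criteria: pd.DataFrame  # k, aic, bic


def _fit_single(values: np.ndarray, k: int, seed: int, n_init: int) -> MixtureFit:
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
    )
    x = values.reshape(-1, 1)
    gm.fit(x)
    return MixtureFit(
        k=k,
        weights=gm.weights_.copy(),
        means=gm.means_.ravel().copy(),
        variances=gm.covariances_.ravel().copy(),
        aic=float(gm.aic(x)),
        bic=float(gm.bic(x)),
        seed=seed,
        converged=bool(gm.converged_),
        _model=gm,
    )


def fit_mixture(
    values: Sequence[float],
    k_candidates: Sequence[int] = range(1, 9),
    seed: int = 0,
    n_init: int = 10,
    improvement_frac: float = 0.02,
) -> MixtureSelection:
    """EM fits for each candidate k with an AIC/BIC table and an elbow pick.

    The automatic selection takes the smallest k whose BIC improvement over
    k-1 falls below ``improvement_frac`` of the k=1 -> k=2 improvement; the
    table is returned so a caller can override the choice. Degenerate
    (all-identical) inputs fall back to a single-component description.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    k_candidates = sorted(k_candidates)
    if np.allclose(values, values[0] if values.size else 0.0):
        fit = MixtureFit(
            k=1,
            weights=np.array([1.0]),
            means=np.array([values[0] if values.size else 0.0]),
            variances=np.array([1e-12]),
            aic=float("nan"),
            bic=float("nan"),
            seed=seed,
            converged=True,
            degenerate=True,
        )
        return MixtureSelection(
            fits={1: fit},
            selected_k=1,
            criteria=pd.DataFrame({"k": [1], "aic": [np.nan], "bic": [np.nan]}),
        )
    if values.size < 10 * max(k_candidates):
        k_candidates = [k for k in k_candidates if values.size >= 10 * k]
        if not k_candidates:
            raise ValueError("too few data points for any candidate k")

    fits = {k: _fit_single(values, k, seed, n_init) for k in k_candidates}
    crit = pd.DataFrame(
        {
            "k": k_candidates,
            "aic": [fits[k].aic for k in k_candidates],
            "bic": [fits[k].bic for k in k_candidates],
        }
    )
    selected = k_candidates[0]
    if len(k_candidates) >= 2:
        bics = crit["bic"].to_numpy()
        base_gain = bics[0] - bics[1]
        if base_gain <= 0:
            selected = k_candidates[0]
        else:
            selected = k_candidates[-1]
            for i in range(1, len(k_candidates)):
                gain = bics[i - 1] - bics[i]
                if gain < improvement_frac * base_gain:
                    selected = k_candidates[i - 1]
                    break
    return MixtureSelection(fits=fits, selected_k=selected, criteria=crit)


def _categories_for(fit: MixtureFit) -> tuple[str, ...]:
    if fit.k == 4:
        return CATEGORIES_4
    if fit.k == 2:
        return CATEGORIES_2
    return tuple(f"C{i + 1}" for i in range(fit.k))


def classify(values, fit: MixtureFit) -> list[EssentialityCall]:
    """Hard-assign each feature to the argmax-posterior component.

    ``values`` maps feature id -> LD. Components are renamed to categories by
    ascending mean. Posterior ties break toward the more essential category.
    """
    if fit._model is None:
        raise ValueError("fit has no underlying model (degenerate fit?)")
    cats = _categories_for(fit)
    order = fit.order  # order[j] = component index of j-th smallest mean
    comp_to_cat = {int(order[j]): cats[j] for j in range(fit.k)}
    ids = list(values.keys() if hasattr(values, "keys") else range(len(values)))
    lds = np.array([values[i] for i in ids], dtype=float)
    defined = ~np.isnan(lds)
    post = np.zeros((len(ids), fit.k))
    if defined.any():
        post[defined] = fit._model.predict_proba(lds[defined].reshape(-1, 1))
    calls = []
    for row, fid in enumerate(ids):
        if not defined[row]:
            continue
        p = post[row]
        # argmax with ties going to the smaller-mean (more essential) component
        best = max(range(fit.k), key=lambda c: (p[c], -fit.means[c]))
        calls.append(
            EssentialityCall(
                feature_id=fid,
                ld=float(lds[row]),
                category=comp_to_cat[best],
                posteriors={comp_to_cat[c]: float(p[c]) for c in range(fit.k)},
            )
        )
    return calls


def classify_binary(values, fit: MixtureFit) -> list[EssentialityCall]:
    """Two-component E/NE calling (same mechanics as :func:`classify`)."""
    if fit.k != 2:
        raise ValueError(f"classify_binary requires a k=2 fit, got k={fit.k}")
    return classify(values, fit)


def collapse_to_binary(category: str) -> str:
    """Map a 4-class category onto the binary scheme (E,F1 -> E; F2,NE -> NE)."""
    return "E" if category in ("E", "F1") else "NE"


def filter_regulatory(
    elements: Sequence[Feature],
    gene_calls: Sequence[EssentialityCall],
    annot: AnnotationSet,
    min_len: int = 5,
    max_repeat: float = 0.25,
) -> list[Feature]:
    """Regulatory elements eligible for essentiality analysis.

    Keeps elements of at least ``min_len`` bp that do not overlap any E/F1
    gene and whose repeated fraction is at most ``max_repeat``.
    """
    ef1 = {
        c.feature_id for c in gene_calls if c.category in ("E", "F1")
    }
    ef1_genes = [annot[g] for g in ef1 if g in annot]
    out = []
    for el in elements:
        if el.length < min_len:
            continue
        if el.pct_repeated > max_repeat:
            continue
        if any(g.overlaps(el.start, el.end) for g in ef1_genes):
            continue
        out.append(el)
    return out


def calls_table(calls: Sequence[EssentialityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"feature_id": c.feature_id, "ld": c.ld, "category": c.category}
        row.update({f"p_{k}": v for k, v in c.posteriors.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature_id")
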