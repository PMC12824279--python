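"""Group-comparison statistics over metric tables, plus PCA projection.

Contrasts between groups (models, conditions, human cohorts) use Welch's
two-sided independent-samples t-test, Benjamini-Hochberg FDR correction
across the whole contrast family, and Cohen's d with pooled (n-1 weighted)
standard deviation.  Percentile ranks place a single score within a
reference distribution; group summaries report t-based confidence
intervals on the mean.  Document-embedding projections use mean-centered
(unscaled) PCA onto the top two axes, one model per writing task.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastResult",
    "PCAProjection",
    "GroupSummary",
    "t_test_ind",
    "fdr_bh",
    "cohens_d",
    "as_score_table",
    "contrast_matrix",
    "percentile_rank",
    "summarize_group",
    "pca_project",
]


@dataclass
class ContrastResult:
    group_a: str
    group_b: str
    t: float
    p: float
    q: float
    d: float
    n_a: int
    n_b: int


@dataclass
class PCAProjection:
    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    labels: list[str] | None = None


GroupSummary = namedtuple("GroupSummary", "mean ci_low ci_high median sd n")


def t_test_ind(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided independent-samples t-test.

    Degenerate variance in both groups: p=1 by convention when the means
    are equal, p=0 with an infinite statistic otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (math.inf if a.mean() > b.mean() else -math.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fdr_bh(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = list(p)
    if not p:
        return []
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized mean difference with pooled (n-1 weighted) SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0.0:
        raise ValueError("Cohen's d undefined: pooled SD is zero")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def as_score_table(
    df: pd.DataFrame,
    metric: str,
    value_col: str = "score",
    id_col: str = "response_id",
) -> pd.DataFrame:
    """Reshape a wide per-item table into the long score-table layout
    ``{item_id, source, condition, metric, value}`` used by the contrast
    machinery; rows with missing values (excluded items) are dropped."""
    out = pd.DataFrame(
        {
            "item_id": df[id_col],
            "source": df["source"],
            "condition": df.get("condition", ""),
            "metric": metric,
            "value": df[value_col],
        }
    )
    return out.dropna(subset=["value"]).reset_index(drop=True)


def contrast_matrix(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "source",
    value_col: str = "value",
) -> list[ContrastResult]:
    """All pairwise group contrasts for one metric, FDR-corrected jointly.

    k groups yield C(k,2) contrasts, ordered by descending group mean
    (the sign of t is consistent with mean(a) - mean(b), so every t is
    non-negative up to sampling order).  q-values come from a single
    Benjamini-Hochberg pass over the whole family.
    """
    if "metric" in table.columns:
        sub = table[table["metric"] == metric]
    else:
        sub = table
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in table")
    values = {
        g: np.asarray(grp[value_col], dtype=float)
        for g, grp in sub.groupby(group_col, sort=False)
    }
    usable = {g: v for g, v in values.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with at least 2 items each")
    order = sorted(usable, key=lambda g: -usable[g].mean())
    results: list[ContrastResult] = []
    pvals: list[float] = []
    for i, ga in enumerate(order):
        for gb in order[i + 1 :]:
            t, p = t_test_ind(usable[ga], usable[gb])
            try:
                d = cohens_d(usable[ga], usable[gb])
            except ValueError:
                d = math.nan
            results.append(
                ContrastResult(
                    group_a=ga,
                    group_b=gb,
                    t=t,
                    p=p,
                    q=math.nan,
                    d=d,
                    n_a=int(usable[ga].size),
                    n_b=int(usable[gb].size),
                )
            )
            pvals.append(p)
    for res, q in zip(results, fdr_bh(pvals)):
        res.q = q
    return results


def percentile_rank(score: float, reference: Sequence[float]) -> float:
    """100 x fraction of reference values strictly below ``score``."""
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference must be non-empty")
    return float(100.0 * np.count_nonzero(ref < score) / ref.size)


def summarize_group(values: Sequence[float], ci_level: float = 0.95) -> GroupSummary:
    """Mean with t-based confidence interval, median and SD.

    The CI half-width is t_{(1+level)/2, n-1} x sd / sqrt(n); with n < 2
    the CI (and SD) are reported absent.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie strictly between 0 and 1")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    mean = float(arr.mean())
    median = float(np.median(arr))
    if arr.size < 2:
        return GroupSummary(mean, None, None, median, None, int(arr.size))
    sd = float(arr.std(ddof=1))
    half = float(sps.t.ppf((1.0 + ci_level) / 2.0, arr.size - 1) * sd / math.sqrt(arr.size))
    return GroupSummary(mean, mean - half, mean + half, median, sd, int(arr.size))


def pca_project(
    doc_vectors,
    n_components: int = 2,
    labels: Sequence[str] | None = None,
) -> PCAProjection:
    """Mean-centered (unscaled) PCA projection onto the top components.

    Deterministic up to a per-axis sign.  Embedding dimensions share units,
    so no variance scaling is applied before the decomposition.
    """
    mat = np.asarray(doc_vectors, dtype=float)
    if mat.ndim != 2:
        raise ValueError("doc_vectors must be a 2-D array (items x dims)")
    if mat.shape[0] < max(3, n_components):
        raise ValueError("need at least 3 items and no fewer items than components")
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(mat)
    lab = list(labels) if labels is not None else None
    if lab is not None and len(lab) != mat.shape[0]:
        raise ValueError("labels length must match number of items")
    return PCAProjection(
        coordinates=coords,
        explained_variance_ratio=model.explained_variance_ratio_,
        labels=lab,
    )
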