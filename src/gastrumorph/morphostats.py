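"""Statistical layer: morphospace construction, PCA, rank-sum comparisons,
variation (robustness) decomposition and internalization efficiency.

Transversal sections live as points in a z-score-normalized morphospace.
For group comparisons the time-independent 4-parameter space is used
(internalization, integrity, furrow depth, maximal cell depth); the
wild-type PCA adds furrow width for five parameters.  Variation within and
between embryos is measured as Euclidean distance between section points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "TIME_INDEPENDENT_PARAMS",
    "WILDTYPE_PCA_PARAMS",
    "MorphospacePoint",
    "PCAResult",
    "VariationSummary",
    "zscore",
    "pca",
    "wilcoxon_rank_sum",
    "significance_stars",
    "compare_groups",
    "variation_decomposition",
    "efficiency",
]

#: the 4 time-independent parameters of the variation morphospace
TIME_INDEPENDENT_PARAMS = ("internalization", "integrity", "furrow_depth", "max_cell_depth")
#: the 5-parameter space of the wild-type PCA
WILDTYPE_PCA_PARAMS = TIME_INDEPENDENT_PARAMS + ("furrow_width",)


@dataclass
class MorphospacePoint:
    """One transversal section embedded in the z-scored morphospace."""

    embryo_id: str
    section_index: int
    group_label: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("morphospace coordinates must be finite")


@dataclass
class PCAResult:
    loadings: np.ndarray  # (n_params, n_components), orthonormal columns
    scores: np.ndarray  # (n_points, n_components)
    variance_fraction: np.ndarray  # per component, sums to <= 1
    parameters: tuple = ()


@dataclass
class VariationSummary:
    """Morphospace variation of one group.

    ``group_variation``: mean Euclidean distance over all unordered section
    pairs in the group.  ``between_embryo``: per embryo, the mean distance of
    its sections to the sections of all other embryos (methods variant), and
    ``between_embryo_centroid``: pairwise distances between embryo centroids
    (figure-legend variant).  ``within_embryo``: per embryo, the standard
    deviation of the pairwise distances among its sections.
    """

    group_label: str
    group_variation: float
    between_embryo: dict
    between_embryo_centroid: dict
    within_embryo: dict


def zscore(matrix, axis: int = 0) -> np.ndarray:
    """Column-wise z-score normalization (mean 0, sample sd 1)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    sd = x.std(axis=axis, ddof=1)
    const = np.where(sd <= 0)[0]
    if const.size:
        raise ValueError(f"constant column(s) at index {const.tolist()}: cannot z-score")
    return (x - x.mean(axis=axis)) / sd


def pca(points: np.ndarray, n_components: int | None = None, parameters=()) -> PCAResult:
    """Principal component analysis of (z-scored) section parameters.

    Components are ordered by descending explained variance with a
    deterministic sign convention (the largest-magnitude loading of each
    component is positive); scores are the data projected on the loadings.
    Components beyond the matrix rank are omitted.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[0] < x.shape[1]:
        raise ValueError("need a 2D matrix with at least as many rows as columns")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (len(x) - 1)
    total = centered.var(axis=0, ddof=1).sum()
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = rank if n_components is None else min(n_components, rank)
    loadings = vt[:k].T
    # sign convention: largest |loading| positive
    for j in range(k):
        idx = np.argmax(np.abs(loadings[:, j]))
        if loadings[idx, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = centered @ loadings
    variance_fraction = eigvals[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        variance_fraction=variance_fraction,
        parameters=tuple(parameters),
    )


def wilcoxon_rank_sum(sample_a, sample_b):
    """Two-sided Wilcoxon rank-sum test; returns ``(rank_sum_a, p)``.

    Exact null enumeration when n + m <= 20 with no ties; otherwise the
    normal approximation with tie and continuity correction (mid-ranks for
    ties).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    return w, float(res.pvalue)


def significance_stars(p: float) -> str:
    """Star convention: ns p>0.05; * p<=0.05; ** p<=0.01; *** p<=0.001;
    **** p<=0.0001."""
    if np.isnan(p):
        return "na"
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def compare_groups(section_table: pd.DataFrame, parameters=TIME_INDEPENDENT_PARAMS, group_col: str = "group_label") -> pd.DataFrame:
    """Per-parameter group medians and pairwise Wilcoxon rank-sum p-values.

    ``section_table`` is tidy (one row per embryo x section).  Returns one
    row per (parameter, group pair) with medians, p and significance stars.
    NaN parameter values (undefined integrity) are dropped per comparison.
    """
    groups = list(dict.fromkeys(section_table[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    rows = []
    for param in parameters:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ga = section_table.loc[section_table[group_col] == groups[i], param].dropna()
                gb = section_table.loc[section_table[group_col] == groups[j], param].dropna()
                if len(ga) < 2 or len(gb) < 2:
                    raise ValueError(
                        f"group with fewer than 2 sections for parameter {param!r}"
                    )
                _, p = wilcoxon_rank_sum(ga.to_numpy(), gb.to_numpy())
                rows.append(
                    {
                        "parameter": param,
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "median_a": float(ga.median()),
                        "median_b": float(gb.median()),
                        "p_value": p,
                        "stars": significance_stars(p),
                    }
                )
    return pd.DataFrame(rows)


def _points_by_embryo(points):
    by_embryo: dict = {}
    for p in points:
        by_embryo.setdefault(p.embryo_id, []).append(p.coords)
    return {k: np.vstack(v) for k, v in by_embryo.items()}


def variation_decomposition(points) -> VariationSummary:
    """Morphospace variation of one group of :class:`MorphospacePoint`.

    See :class:`VariationSummary` for the three measures; both between-embryo
    variants (section-to-section averages and centroid distances) are
    reported.
    """
    points = list(points)
    if not points:
        raise ValueError("no morphospace points")
    group = points[0].group_label
    coords = np.vstack([p.coords for p in points])
    group_variation = float(pdist(coords).mean()) if len(coords) > 1 else 0.0
    by_embryo = _points_by_embryo(points)
    between = {}
    within = {}
    if len(by_embryo) > 1:
        for eid, mine in by_embryo.items():
            others = np.vstack([v for k, v in by_embryo.items() if k != eid])
            between[eid] = float(cdist(mine, others).mean())
    centroids = {eid: v.mean(axis=0) for eid, v in by_embryo.items()}
    centroid_between = {}
    eids = list(centroids)
    for i in range(len(eids)):
        for j in range(i + 1, len(eids)):
            centroid_between[(eids[i], eids[j])] = float(
                np.linalg.norm(centroids[eids[i]] - centroids[eids[j]])
            )
    for eid, mine in by_embryo.items():
        if len(mine) < 2:
            continue  # within-embryo variation needs >= 2 sections
        d = pdist(mine)
        within[eid] = float(d.std(ddof=0)) if len(d) > 1 else 0.0
    return VariationSummary(
        group_label=group,
        group_variation=group_variation,
        between_embryo=between,
        between_embryo_centroid=centroid_between,
        within_embryo=within,
    )


def efficiency(embryo_table: pd.DataFrame, gbe_window=(15.0, 25.0), group_col: str = "group_label") -> pd.DataFrame:
    """Internalization efficiency per embryo at a comparable stage.

    Embryos are filtered to the germband-extension window (default 15-25%
    GBE); efficiency is the percentage of internalized cells in the ROI.
    Requires columns ``gbe_percent``, ``n_roi``, ``n_internalized``.
    """
    lo, hi = gbe_window
    sel = embryo_table[
        (embryo_table["gbe_percent"] >= lo) & (embryo_table["gbe_percent"] <= hi)
    ].copy()
    if sel.empty:
        raise ValueError(f"no embryo inside the {lo}-{hi}% GBE window")
    sel["efficiency_percent"] = 100.0 * sel["n_internalized"] / sel["n_roi"]
    cols = ["embryo_id", group_col, "gbe_percent", "efficiency_percent"]
    return sel[[c for c in cols if c in sel.columns]].reset_index(drop=True)
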