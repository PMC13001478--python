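"""Effect sizes, heterogeneity, and single-cell clustering.

With thousands of single cells per group, p-values saturate, so group
comparisons use Cohen's d,

    d = (M1 - M2) / sqrt((SD1^2 + SD2^2) / 2),

the standardized mean difference with the root-mean-square of the two
sample SDs as denominator, bucketed into the conventional categories
(|d| < 0.2 none, 0.2-0.5 small, 0.5-0.8 medium, >= 0.8 large; the lower
boundary of each band belongs to that band).  Within-population
heterogeneity is summarized by the coefficient of variation SD/mean.
Cells are clustered hierarchically on z-scored OMI variables with Ward's
minimum-variance linkage and Euclidean distance; annotations (condition,
donor, cell type) ride along but never enter the distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .simulate import OMI_VARIABLES

#: |d| thresholds for the effect-size categories.
D_CATEGORIES = [(0.2, "none"), (0.5, "small"), (0.8, "medium"), (np.inf, "large")]

#: Below this per-group cell count, effect sizes are flagged as undersampled.
MIN_CELLS_PER_GROUP = 100

#: Embedding parameters recorded for optional use with an external UMAP
#: implementation when plotting single-cell heterogeneity; no embedding is
#: computed by this package.
UMAP_PARAMS = {"metric": "euclidean", "n_neighbors": 6, "min_dist": 0.6}


@dataclass
class EffectSize:
    d: float
    category: str
    direction: str  # "increase" | "decrease" | "none" (sign of M1 - M2)
    n1: int
    n2: int
    m1: float
    m2: float
    sd1: float
    sd2: float


def categorize_d(d: float) -> str:
    if not np.isfinite(d):
        return "undefined"
    for thr, name in D_CATEGORIES:
        if abs(d) < thr:
            return name
    return "large"


def cohens_d(group1, group2, warn_small_n: bool = True) -> EffectSize:
    """Cohen's d of group1 relative to group2.

    A positive d (direction "increase") means group1's mean exceeds
    group2's.  Groups below ``MIN_CELLS_PER_GROUP`` cells trigger a
    sampling-error warning, not an error.  If both SDs are zero the effect
    size is undefined (NaN, category "undefined").
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    if warn_small_n and (g1.size < MIN_CELLS_PER_GROUP or g2.size < MIN_CELLS_PER_GROUP):
        warnings.warn(
            f"group sizes ({g1.size}, {g2.size}) below the "
            f"{MIN_CELLS_PER_GROUP}-cell guideline; d is noisy",
            stacklevel=2,
        )
    m1, m2 = g1.mean(), g2.mean()
    sd1, sd2 = g1.std(ddof=1), g2.std(ddof=1)
    denom = np.sqrt((sd1**2 + sd2**2) / 2.0)
    d = (m1 - m2) / denom if denom > 0 else np.nan
    direction = "none"
    if np.isfinite(d) and d != 0:
        direction = "increase" if d > 0 else "decrease"
    return EffectSize(
        d=float(d),
        category=categorize_d(d),
        direction=direction,
        n1=int(g1.size),
        n2=int(g2.size),
        m1=float(m1),
        m2=float(m2),
        sd1=float(sd1),
        sd2=float(sd2),
    )


def coefficient_of_variation(values) -> float:
    """SD/mean with the sample (n-1) SD; NaN for nonpositive means."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean <= 0:
        warnings.warn("nonpositive mean; COV undefined", stacklevel=2)
        return np.nan
    return float(v.std(ddof=1) / mean)


def effect_size_table(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    group_column: str = "condition",
    group1: str = "activated",
    group2: str = "quiescent",
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Cohen's d of group1 vs group2 for each variable, optionally stratified.

    ``by`` (e.g. ["cell_type", "donor"]) computes d within each stratum;
    None pools all cells.  Rows: strata; columns: variable d / category /
    direction, mirroring an effect-size heatmap.
    """
    variables = variables or OMI_VARIABLES
    if by is None:
        strata = [({"stratum": "all"}, table)]
    else:
        strata = [
            (dict(zip(by, key if isinstance(key, tuple) else (key,))), sub)
            for key, sub in table.groupby(list(by), observed=True)
        ]
    rows = []
    for row_key, sub in strata:
        row = dict(row_key)
        for var in variables:
            g1 = sub.loc[sub[group_column] == group1, var]
            g2 = sub.loc[sub[group_column] == group2, var]
            if len(g1) < 2 or len(g2) < 2:
                row[f"{var}_d"] = np.nan
                row[f"{var}_category"] = "undefined"
                row[f"{var}_direction"] = "none"
                continue
            es = cohens_d(g1, g2, warn_small_n=False)
            row[f"{var}_d"] = es.d
            row[f"{var}_category"] = es.category
            row[f"{var}_direction"] = es.direction
        rows.append(row)
    return pd.DataFrame(rows)


def heterogeneity_table(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    by: list[str] = ("cell_type", "condition"),
) -> pd.DataFrame:
    """Per (stratum, variable): mean, sample SD, COV = SD/mean, and n."""
    variables = variables or OMI_VARIABLES
    rows = []
    for key, sub in table.groupby(list(by), observed=True):
        key_t = key if isinstance(key, tuple) else (key,)
        for var in variables:
            v = sub[var].to_numpy(dtype=float)
            if v.size < 2:
                continue
            mean, sd = v.mean(), v.std(ddof=1)
            rows.append(
                {
                    **dict(zip(by, key_t)),
                    "variable": var,
                    "mean": mean,
                    "sd": sd,
                    "cov": sd / mean if mean > 0 else np.nan,
                    "n": int(v.size),
                }
            )
    return pd.DataFrame(rows)


def zscore_features(
    table: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each variable to mean 0, sample SD 1 across all cells.

    Returns (z-scored matrix, scaling table with per-variable mean and SD
    for exact inversion).  Zero-variance columns are dropped with a warning.
    """
    variables = variables or OMI_VARIABLES
    x = table[variables].astype(float)
    if x.isna().any().any():
        raise ValueError("missing values; apply QC before z-scoring")
    mean = x.mean()
    sd = x.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(sd.index[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    z = (x.loc[:, keep] - mean[keep]) / sd[keep]
    scale = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    return z, scale


def ward_cluster(
    z: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    n_clusters: int = 2,
) -> dict:
    """Ward/Euclidean agglomerative clustering of z-scored cells.

    Annotations are carried through to the output untouched and never
    contribute to distances.  Returns the scipy linkage matrix, flat cluster
    assignments at the requested cut (default the first split, k=2), and a
    Newick rendering of the dendrogram.
    """
    x = np.asarray(z, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(x).all():
        raise ValueError("missing values; apply QC before clustering")
    lm = linkage(x, method="ward", metric="euclidean")
    assign = fcluster(lm, t=n_clusters, criterion="maxclust")
    out = {
        "linkage": lm,
        "clusters": assign,
        "newick": linkage_to_newick(lm, [str(i) for i in range(x.shape[0])]),
    }
    if annotations is not None:
        if len(annotations) != x.shape[0]:
            raise ValueError("annotations must align with the clustered rows")
        out["annotations"] = annotations.reset_index(drop=True)
    return out


def linkage_to_newick(lm: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = lm.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    trees = {i: leaf_names[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(lm):
        a, b = int(a), int(b)
        la, lb = h - heights[a], h - heights[b]
        trees[n + k] = f"({trees.pop(a)}:{la:.6g},{trees.pop(b)}:{lb:.6g})"
        heights[n + k] = h
    return trees[2 * n - 2] + ";"
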