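"""Ward hierarchical classification of species germination profiles.

Species are clustered on their (T0, Topt, Tmax, Psi_b) trait vectors with
the Ward criterion in squared-Euclidean geometry: at each step the pair of
clusters is merged whose union minimises the increase in total
within-cluster variance,

    delta(A, B) = |A|*|B| / (|A|+|B|) * ||centroid(A) - centroid(B)||^2,

and that increase is recorded as the merge height. T0 (rather than the
regression-based Tb) represents the low-temperature limit because it is
estimated more precisely. Features are raw degC/MPa by default — the group
summary tables are on raw scales — with an optional z-score standardisation
since mixing units is statistically questionable. Ties between equal-cost
merges are broken deterministically by the lowest pair of cluster ids.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .types import (
    EstimationError,
    FunctionalGrouping,
    MergeRecord,
    ValidationError,
)

DEFAULT_FEATURES = ("t0", "topt", "tmax", "psi_b")
DEFAULT_K = 5


def ward_linkage(X: np.ndarray) -> list[MergeRecord]:
    """Agglomerative Ward merge sequence for observation matrix ``X`` (n x p).

    Cluster ids follow the scipy convention (0..n-1 singletons, merge i
    creates id n+i); heights are the within-variance increase of each merge.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 1:
        raise ValidationError("expected a 2-D observation matrix")
    n = len(X)
    centroids = {i: X[i].copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    merges: list[MergeRecord] = []
    next_id = n
    while len(centroids) > 1:
        best = None
        ids = sorted(centroids)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                na, nb = sizes[a], sizes[b]
                diff = centroids[a] - centroids[b]
                cost = na * nb / (na + nb) * float(diff @ diff)
                if best is None or cost < best[0]:  # strict <: earliest (lowest) pair wins ties
                    best = (cost, a, b)
        cost, a, b = best
        na, nb = sizes[a], sizes[b]
        merged = (na * centroids[a] + nb * centroids[b]) / (na + nb)
        del centroids[a], centroids[b], sizes[a], sizes[b]
        centroids[next_id] = merged
        sizes[next_id] = na + nb
        merges.append(MergeRecord(left=a, right=b, height=cost, size=na + nb))
        next_id += 1
    return merges


def cut_linkage(merges: Sequence[MergeRecord], n: int, k: int) -> np.ndarray:
    """Labels 1..k from the first n-k merges; groups numbered by first-member order."""
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, m in enumerate(merges[: n - k]):
        new_id = n + i
        parent[find(m.left)] = new_id
        parent[find(m.right)] = new_id
    roots = [find(i) for i in range(n)]
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return labels


def ward_cluster(
    profiles: pd.DataFrame,
    k: int = DEFAULT_K,
    standardize: bool = False,
    features: Sequence[str] = DEFAULT_FEATURES,
    id_col: str = "species_id",
) -> FunctionalGrouping:
    """Ward classification of a species-profile table cut at ``k`` groups.

    ``profiles`` must carry ``id_col`` plus finite values in every feature
    column; missing features raise a named error.
    """
    for f in features:
        if f not in profiles.columns:
            raise ValidationError(f"missing clustering feature column {f!r}")
    X = profiles[list(features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = profiles.loc[~np.isfinite(X).all(axis=1), id_col].tolist()
        raise ValidationError(f"non-finite clustering features for species: {bad}")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    merges = ward_linkage(X)
    labels = cut_linkage(merges, len(X), k)
    return FunctionalGrouping(
        k=k,
        labels=dict(zip(profiles[id_col].astype(str), (int(v) for v in labels))),
        linkage=tuple(merges),
        feature_names=tuple(features),
        standardized=standardize,
    )


def group_summary(
    grouping: FunctionalGrouping,
    profiles: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    id_col: str = "species_id",
) -> pd.DataFrame:
    """Per-group mean +/- sample SD of each feature (singleton groups get SD 0).

    Returns a frame indexed by group with ``<feature>_mean``/``<feature>_sd``
    columns at full precision plus display-rounded ``*_1dp`` columns.
    """
    df = profiles.copy()
    df["group"] = df[id_col].astype(str).map(grouping.labels)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), id_col].tolist()
        raise ValidationError(f"species absent from grouping: {missing}")
    out = {}
    for f in features:
        grp = df.groupby("group")[f]
        out[f"{f}_mean"] = grp.mean()
        out[f"{f}_sd"] = grp.std(ddof=1).fillna(0.0)
    res = pd.DataFrame(out)
    res["n_species"] = df.groupby("group").size()
    res["singleton"] = res["n_species"] == 1
    for f in features:
        res[f"{f}_mean_1dp"] = res[f"{f}_mean"].round(1)
        res[f"{f}_sd_1dp"] = res[f"{f}_sd"].round(1)
    return res


def family_summary(profiles: pd.DataFrame, feature_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-family mean +/- sample SD of each numeric trait column."""
    if "family" not in profiles.columns:
        raise ValidationError("profiles must carry a 'family' column")
    if feature_cols is None:
        feature_cols = [
            c for c in profiles.columns
            if c not in ("family",) and pd.api.types.is_numeric_dtype(profiles[c])
        ]
    out = {}
    grp = profiles.groupby("family")
    for f in feature_cols:
        out[f"{f}_mean"] = grp[f].mean()
        out[f"{f}_sd"] = grp[f].std(ddof=1).fillna(0.0)
    res = pd.DataFrame(out)
    res["n_species"] = grp.size()
    return res


def trait_correlation(x, y) -> tuple[float, float, float]:
    """Pearson correlation between two trait vectors: (r, r^2, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("trait vectors must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EstimationError("correlation undefined for a zero-variance trait")
    res = pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def multiple_r_squared(X, y) -> float:
    """R^2 of an OLS fit of ``y`` on the columns of ``X`` (with intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise EstimationError("R^2 undefined for a zero-variance response")
    return 1.0 - float(np.sum(resid**2)) / tss


def linkage_to_newick(
    merges: Sequence[MergeRecord], leaf_names: Sequence[str]
) -> str:
    """Newick serialisation of the dendrogram, merge heights as node depths.

    Branch lengths are the difference between a parent merge's height and
    each child's own merge height (0 for leaves).
    """
    n = len(leaf_names)
    height = {i: 0.0 for i in range(n)}
    node = {i: (str(leaf_names[i]), 0.0) for i in range(n)}
    for i, m in enumerate(merges):
        for child in (m.left, m.right):
            if child not in node:
                raise ValidationError(f"merge references unknown cluster id {child}")
        ln, lh = node[m.left][0], height[m.left]
        rn, rh = node[m.right][0], height[m.right]
        rep = f"({ln}:{max(m.height - lh, 0.0):.6g},{rn}:{max(m.height - rh, 0.0):.6g})"
        node[n + i] = (rep, m.height)
        height[n + i] = m.height
    root = n + len(merges) - 1 if merges else 0
    return node[root][0] + ";"
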