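"""Spatial neighborhood statistics: K-nearest-neighbor phenotype distance
profiles, the symmetric pairwise distance rank (PDR), the PDR feature map,
per-ROI neighbor-distance summaries with Welch's ANOVA, and RGB interaction
zones.

The PDR pipeline: take each cell's K = 50 nearest neighbors (within its own
ROI — ROIs are physically separate tissue cores), record the mean distance
from the cell to the neighbors of each phenotype, average those per source
phenotype over the selected ROIs to get a (generally asymmetric) mean
distance matrix D[A][B] in µm, rank all defined ordered off-diagonal entries
of D (fractional ranks for ties), scale ranks affinely to the unit interval,
and symmetrize by the geometric mean of rank(A, B) and rank(B, A). 0 marks
the closest interacting pair, 1 the furthest. Because PDR depends on D only
through ranks, it is invariant to any strictly increasing transform of the
distances — in particular to a uniform rescaling of the coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborSet",
    "SpatialConfig",
    "knn",
    "phenotype_profiles",
    "mean_distance_matrix",
    "pdr",
    "pdr_feature_map",
    "neighbor_distance_summary",
    "welch_anova",
    "interaction_zones",
]


@dataclass
class NeighborSet:
    """Per-cell K nearest neighbors within the same ROI.

    ``indices`` holds global row indices into the originating cell table,
    padded with -1 where a ROI has fewer than K other cells; ``distances``
    carries the matching Euclidean distances in µm (NaN padding), sorted
    non-decreasing per row. Self is always excluded.
    """

    indices: np.ndarray  # (n_cells, K) int, -1 padded
    distances: np.ndarray  # (n_cells, K) float, NaN padded
    k: int

    def n_neighbors(self) -> np.ndarray:
        return (self.indices >= 0).sum(axis=1)


@dataclass
class SpatialConfig:
    """Parameters of the spatial stage."""

    k: int = 50  # neighbors per cell
    condition: str | None = None  # restrict to one condition's ROIs
    phenotypes: tuple[str, ...] | None = None  # phenotype subset for D/PDR
    tau: float = 25.0  # zone decay length, µm (~1-2 cell diameters)
    min_contributing: int = 1  # min cells behind a D[A][B] entry

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def knn(table: pd.DataFrame, k: int = 50) -> NeighborSet:
    """Exact Euclidean K nearest neighbors of every cell, computed within
    each ROI independently; K truncates to n_roi - 1. Ties are broken by
    (distance, lower global row index). A single-cell ROI yields an empty,
    flagged neighbor list."""
    if k < 1:
        raise ValueError("K must be >= 1")
    xy = table[["x_um", "y_um"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    n = len(table)
    roi_arr = table["roi_id"].to_numpy()
    indices = np.full((n, k), -1, dtype=np.int64)
    distances = np.full((n, k), np.nan)
    for roi in pd.unique(roi_arr):
        rows = np.nonzero(roi_arr == roi)[0]
        pts = xy[rows]
        m = len(rows)
        if m == 1:
            warnings.warn(f"ROI {roi!r} has a single cell; empty neighbor list")
            continue
        kk = min(k, m - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(pts)
        dist, idx = nn.kneighbors(pts)
        for a in range(m):
            # drop self; with coincident points sklearn may or may not list
            # self first, so filter by identity and re-sort with the
            # (distance, lower row index) tie-break
            keep = idx[a] != a
            d, g = dist[a][keep], rows[idx[a][keep]]
            order = np.lexsort((g, d))[:kk]
            indices[rows[a], :kk] = g[order]
            distances[rows[a], :kk] = d[order]
    return NeighborSet(indices=indices, distances=distances, k=k)


def phenotype_profiles(
    neighbors: NeighborSet,
    labels: np.ndarray | pd.Series,
    phenotype_names: list | None = None,
) -> pd.DataFrame:
    """Per cell, the mean distance (µm) to the neighbors of each phenotype
    within its NeighborSet; NaN where the phenotype is absent from the
    neighborhood."""
    labels = np.asarray(labels, dtype=object)
    valid = neighbors.indices >= 0
    nbr_labels = np.empty(neighbors.indices.shape, dtype=object)
    nbr_labels[valid] = labels[neighbors.indices[valid]]
    if pd.isna(nbr_labels[valid]).any():
        raise ValueError("unlabeled cell among neighbors")
    if phenotype_names is None:
        phenotype_names = sorted(pd.unique(labels[~pd.isna(labels)]))
    d = neighbors.distances
    out = {}
    for p in phenotype_names:
        mask = valid & (nbr_labels == p)
        cnt = mask.sum(axis=1)
        s = np.where(mask, d, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[p] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(out)


def mean_distance_matrix(
    profiles: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    roi_ids: np.ndarray | pd.Series,
    rois: list | None = None,
    phenotypes: list | None = None,
    min_contributing: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool per-cell profiles into D[A][B]: the mean distance from phenotype
    A cells (in the selected ROIs) to phenotype B neighbors, with n[A][B]
    the count of contributing cells. Entries backed by fewer than
    ``min_contributing`` cells are set missing. Generally asymmetric."""
    labels = np.asarray(labels, dtype=object)
    roi_ids = np.asarray(roi_ids, dtype=object)
    sel = np.ones(len(labels), dtype=bool)
    if rois is not None:
        sel = np.isin(roi_ids, list(rois))
        if not sel.any():
            raise ValueError("empty ROI selection")
    if phenotypes is None:
        phenotypes = [p for p in profiles.columns if (labels[sel] == p).any()]
    D = pd.DataFrame(np.nan, index=phenotypes, columns=phenotypes, dtype=float)
    N = pd.DataFrame(0, index=phenotypes, columns=phenotypes, dtype=int)
    for a in phenotypes:
        rows = sel & (labels == a)
        if not rows.any():
            continue
        sub = profiles.loc[rows, phenotypes]
        n = sub.notna().sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = sub.mean(axis=0, skipna=True)
        N.loc[a] = n.to_numpy()
        D.loc[a] = np.where(n.to_numpy() >= min_contributing, m.to_numpy(), np.nan)
    D.index.name = D.columns.name = "phenotype"
    N.index.name = N.columns.name = "phenotype"
    return D, N


def pdr(D: pd.DataFrame) -> pd.DataFrame:
    """Symmetric pairwise distance rank from a mean-distance matrix.

    All defined ordered off-diagonal entries of D receive fractional
    (average-tie) ranks, affinely scaled so the minimum maps to 0 and the
    maximum to 1; PDR[A][B] = sqrt(r(A, B) * r(B, A)). Missing where either
    ordered entry is undefined; the diagonal is missing by convention. When
    every defined entry is tied the scaling is degenerate and a single
    common value of 0.5 is returned.
    """
    phen = list(D.index)
    if list(D.columns) != phen:
        raise ValueError("D must be square with matching index/columns")
    vals = D.to_numpy(float).copy()
    np.fill_diagonal(vals, np.nan)
    defined = ~np.isnan(vals)
    flat = vals[defined]
    if flat.size < 2:
        raise ValueError("need at least 2 defined ordered off-diagonal entries")
    ranks = stats.rankdata(flat, method="average")
    if ranks.max() > ranks.min():
        scaled = (ranks - ranks.min()) / (ranks.max() - ranks.min())
    else:
        scaled = np.full_like(ranks, 0.5)
    R = np.full(vals.shape, np.nan)
    R[defined] = scaled
    out = np.sqrt(R * R.T)  # NaN propagates where either direction missing
    return pd.DataFrame(out, index=D.index.copy(), columns=D.columns.copy())


def pdr_feature_map(
    pdr_matrix: pd.DataFrame,
    frequencies: pd.Series | dict,
    seed: int = 0,
    embedder=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node-link summary of the PDR matrix.

    Nodes are phenotypes placed by a 2-D embedding of the PDR row vectors
    (UMAP by default, seeded); node size is proportional to phenotype
    frequency, node color is the row-mean PDR, and edge weight is 1 - PDR
    (close pairs draw heavy, opaque edges). Missing PDR entries are imputed
    as 1 (maximally distant) for the embedding, with a warning. With fewer
    than 3 phenotypes the embedding is degenerate and a deterministic
    circular layout is used instead (flagged by a warning).

    Returns (nodes, edges): nodes with columns x, y, size, color; edges with
    phenotype_a, phenotype_b, weight.
    """
    phen = list(pdr_matrix.index)
    mat = pdr_matrix.to_numpy(float).copy()
    np.fill_diagonal(mat, 0.0)
    if np.isnan(mat).any():
        warnings.warn("missing PDR entries imputed as 1 for the feature map")
        mat = np.where(np.isnan(mat), 1.0, mat)
    n = len(phen)
    if n < 3:
        warnings.warn("fewer than 3 phenotypes: circular layout fallback")
        ang = 2 * np.pi * np.arange(n) / max(n, 1)
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
    elif embedder is not None:
        coords = np.asarray(embedder(mat))
    else:
        import umap

        nn = max(2, min(5, n - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = umap.UMAP(
                n_neighbors=nn, n_components=2, init="random",
                random_state=seed, min_dist=0.3,
            ).fit_transform(mat)
    freq = pd.Series(frequencies, dtype=float).reindex(phen)
    row_mean = pd.Series(
        np.nanmean(np.where(np.eye(n, dtype=bool), np.nan, mat), axis=1), index=phen
    )
    nodes = pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "size": freq / freq.sum(),
            "color": row_mean,
        },
        index=pd.Index(phen, name="phenotype"),
    )
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append((phen[i], phen[j], 1.0 - mat[i, j]))
    edges = pd.DataFrame(rows, columns=["phenotype_a", "phenotype_b", "weight"])
    return nodes, edges


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's one-way ANOVA for unequal variances.

    Returns (F, df1, df2, p) with the Welch–Satterthwaite degrees of
    freedom. All-equal group means give F = 0, p = 1 even when the
    within-group variances vanish.
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([len(g) for g in groups], float)
    if (n < 2).any():
        raise ValueError("each group needs at least 2 values")
    means = np.array([g.mean() for g in groups])
    var = np.array([g.var(ddof=1) for g in groups])
    if np.allclose(means, means[0]) and np.all(var == 0):
        return 0.0, float(k - 1), float("inf"), 1.0
    if np.any(var == 0):
        raise ValueError("a group has zero variance; Welch weights undefined")
    w = n / var
    mw = (w * means).sum() / w.sum()
    f_num = ((w * (means - mw) ** 2).sum()) / (k - 1)
    lam = (((1 - w / w.sum()) ** 2) / (n - 1)).sum() * 3.0 / (k**2 - 1)
    f_den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
    F = f_num / f_den
    df1 = float(k - 1)
    df2 = 1.0 / lam
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, float(df2), p


def neighbor_distance_summary(
    profiles: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    roi_ids: np.ndarray | pd.Series,
    source_phenotype: str,
    rois: list | None = None,
    neighbor_phenotypes: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI mean distance from ``source_phenotype`` cells to each
    neighbor phenotype (no pooling across ROIs), plus Welch's ANOVA across
    the neighbor-phenotype groups of per-ROI means.

    Returns (per_roi, anova): per_roi is ROIs × neighbor phenotypes; anova
    is a one-row frame with F, df1, df2, p.
    """
    labels = np.asarray(labels, dtype=object)
    roi_ids = np.asarray(roi_ids, dtype=object)
    if rois is None:
        rois = sorted(pd.unique(roi_ids))
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    if neighbor_phenotypes is None:
        neighbor_phenotypes = [p for p in profiles.columns if p != source_phenotype]
    if len(neighbor_phenotypes) < 2:
        raise ValueError("need at least 2 neighbor phenotypes")
    per_roi = pd.DataFrame(np.nan, index=list(rois), columns=neighbor_phenotypes)
    for roi in rois:
        rows = (roi_ids == roi) & (labels == source_phenotype)
        if not rows.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_roi.loc[roi] = profiles.loc[rows, neighbor_phenotypes].mean(axis=0).to_numpy()
    groups = []
    for p in neighbor_phenotypes:
        g = per_roi[p].dropna().to_numpy()
        if len(g) < 2:
            raise ValueError(f"neighbor phenotype {p!r} has < 2 defined ROI values")
        groups.append(g)
    F, df1, df2, pval = welch_anova(groups)
    anova = pd.DataFrame({"F": [F], "df1": [df1], "df2": [df2], "p": [pval]})
    per_roi.index.name = "roi_id"
    return per_roi, anova


def interaction_zones(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    ref_phenotypes: tuple[str, str, str],
    tau: float = 25.0,
    roi: str | None = None,
) -> pd.DataFrame:
    """Per-cell RGB interaction-zone channels.

    Channel c of a cell is exp(-d_c / tau) with d_c the distance (µm) to the
    nearest cell of reference phenotype c in the same ROI; a reference
    cell's own channel is 1 (its nearest same-phenotype cell is itself at
    distance 0). Cells close to all three references approach white. A
    reference phenotype absent from a ROI zeroes that channel with a
    warning. Returns a frame aligned to ``table`` with columns R, G, B.
    """
    if len(ref_phenotypes) != 3:
        raise ValueError("exactly 3 reference phenotypes required")
    if tau <= 0:
        raise ValueError("tau must be positive")
    labels = np.asarray(labels, dtype=object)
    sub = table if roi is None else table[table["roi_id"] == roi]
    rgb = np.zeros((len(sub), 3))
    xy = sub[["x_um", "y_um"]].to_numpy(float)
    sub_labels = labels if roi is None else labels[(table["roi_id"] == roi).to_numpy()]
    roi_arr = sub["roi_id"].to_numpy()
    for roi_id in pd.unique(roi_arr):
        m = roi_arr == roi_id
        pts = xy[m]
        lab = sub_labels[m]
        for c, ref in enumerate(ref_phenotypes):
            ref_pts = pts[lab == ref]
            if len(ref_pts) == 0:
                warnings.warn(f"reference phenotype {ref!r} absent from ROI {roi_id!r}")
                rgb[m, c] = 0.0
                continue
            nn = NearestNeighbors(n_neighbors=1).fit(ref_pts)
            d = nn.kneighbors(pts)[0][:, 0]
            rgb[m, c] = np.exp(-d / tau)
    out = pd.DataFrame(rgb, columns=["R", "G", "B"], index=sub.index)
    return out
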