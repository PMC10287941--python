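"""Cell-population peak calling on a 2D embedding by RTS-weighted density.

Each cell is weighted by the RTS of its highest-expressed priority gene and
a weighted Gaussian kernel density is estimated over the embedding.  Ten
contour (superlevel) thresholds are placed on the density; at each
threshold, DBSCAN groups the cells above it into spatially separated
clusters.  A *peak* is an innermost qualifying cluster — one with no
qualifying cluster from the next higher contour level nested inside it —
and represents a candidate distinct cell population.  Each peak is labelled
by its anchor gene, the priority gene with the highest mean expression
among its member cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .rts import PriorityGeneSet

logger = logging.getLogger("triage")


# ---------------------------------------------------------------------------
# cell weights

def assign_cell_weights(expr: pd.DataFrame,
                        priority: PriorityGeneSet) -> pd.DataFrame:
    """Per-cell weight = RTS of the highest-expressed priority gene.

    Among priority genes with expression > 0 in a cell, the maximum-
    expression gene wins (ties broken by higher RTS, then lexicographic
    gene id); the cell's weight is that gene's RTS and the gene is recorded
    as ``anchor_candidate``.  Cells expressing no priority gene get weight 0
    and no candidate.

    Returns a DataFrame indexed by cell with columns ``weight`` and
    ``anchor_candidate``.
    """
    if len(priority) == 0:
        raise ValidationError("priority gene set is empty")
    genes = [g for g in priority.genes if g in expr.index]
    if not genes:
        raise ValidationError("no priority gene present in expression matrix")
    sub = expr.loc[genes]
    rts = priority.rts.loc[genes].values
    # stable tie-break ordering: sort candidate rows once by (rts desc,
    # gene_id asc) so that argmax over equal expression picks the right one
    row_order = np.lexsort((np.array(genes), -rts))
    sub = sub.iloc[row_order]
    rts_sorted = rts[row_order]
    gene_sorted = np.array(genes)[row_order]

    vals = sub.values
    best = np.argmax(vals, axis=0)          # first max in tie-break order
    expressed = vals[best, np.arange(vals.shape[1])] > 0
    weights = np.where(expressed, rts_sorted[best], 0.0)
    anchors = np.where(expressed, gene_sorted[best], None)
    return pd.DataFrame({"weight": weights, "anchor_candidate": anchors},
                        index=expr.columns)


# ---------------------------------------------------------------------------
# weighted KDE

def kde_bandwidth(n: int, d: int = 2) -> float:
    """Scott's-rule bandwidth rescaled for single-cell embeddings:
    ``h = 0.3 * n**(-1/(d+4))``."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return 0.3 * float(n) ** (-1.0 / (d + 4))


@dataclass
class DensityModel:
    """Weighted Gaussian KDE over a 2D embedding.

    ``f(x) = sum_i w_i/(sum w) * (2*pi*h^2)^-1 * exp(-||x - x_i||^2 / (2 h^2))``

    Weights are normalised to sum to one so the density integrates to 1.
    ``cell_density`` holds the density evaluated at each cell's own
    coordinates.
    """

    points: np.ndarray                 # (n, 2)
    weights: np.ndarray                # (n,), normalised
    bandwidth: float
    cell_ids: list[str]
    cell_density: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cell_density = self.evaluate(self.points)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def evaluate(self, x: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Density at query points ``x`` (m, 2)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h2 = self.bandwidth ** 2
        norm = 1.0 / (2.0 * np.pi * h2)
        out = np.empty(x.shape[0])
        for lo in range(0, x.shape[0], chunk):
            q = x[lo:lo + chunk]
            d2 = ((q[:, None, :] - self.points[None, :, :]) ** 2).sum(-1)
            out[lo:lo + chunk] = norm * (
                np.exp(-d2 / (2.0 * h2)) @ self.weights)
        return out

    def grid(self, n_grid: int = 200, pad: float = 3.0):
        """Raster of the density for contour plotting.

        Returns ``(xs, ys, Z)`` where ``Z[i, j]`` is the density at
        ``(xs[j], ys[i])``; the grid extends ``pad`` bandwidths beyond the
        data range.
        """
        lo = self.points.min(axis=0) - pad * self.bandwidth
        hi = self.points.max(axis=0) + pad * self.bandwidth
        xs = np.linspace(lo[0], hi[0], n_grid)
        ys = np.linspace(lo[1], hi[1], n_grid)
        xx, yy = np.meshgrid(xs, ys)
        z = self.evaluate(np.column_stack([xx.ravel(), yy.ravel()]))
        return xs, ys, z.reshape(n_grid, n_grid)


def weighted_kde(embedding: pd.DataFrame, weights, h: float) -> DensityModel:
    """Fit the RTS-weighted KDE on a cells x 2 embedding.

    ``weights`` is a per-cell Series/array (or the frame produced by
    :func:`assign_cell_weights`); all-zero weights raise a
    "no priority signal" error.
    """
    if h <= 0:
        raise ValidationError("bandwidth must be positive")
    if isinstance(weights, pd.DataFrame):
        weights = weights["weight"]
    if isinstance(weights, pd.Series):
        weights = weights.reindex(embedding.index)
        if weights.isna().any():
            raise ValidationError("weights missing for some cells")
        w = weights.values.astype(float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != len(embedding):
            raise ValidationError("weights length does not match embedding")
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValidationError("no priority signal: all cell weights are zero")
    return DensityModel(points=embedding[["x", "y"]].values.astype(float),
                        weights=w / total, bandwidth=float(h),
                        cell_ids=list(embedding.index))


# ---------------------------------------------------------------------------
# superlevel-set clustering

@dataclass
class SuperlevelClustering:
    """DBSCAN labellings of the cells above each contour threshold.

    ``labels[k]`` is an int array over all cells: cluster id (>= 0) for
    cells above ``thresholds[k]``, -1 for noise at that level, -2 for cells
    below the threshold.
    """

    thresholds: np.ndarray
    labels: list[np.ndarray]
    eps: float
    min_samples: int
    cell_ids: list[str]


def default_eps(embedding: pd.DataFrame, factor: float = 3.0) -> float:
    """``factor`` x the median nearest-neighbour distance of all cells."""
    nn = NearestNeighbors(n_neighbors=2).fit(embedding[["x", "y"]].values)
    dist, _ = nn.kneighbors()
    return factor * float(np.median(dist[:, -1]))


def superlevel_clusters(density: DensityModel, embedding: pd.DataFrame,
                        n_levels: int = 10, eps: float | None = None,
                        min_samples: int = 5,
                        spacing: str = "linear") -> SuperlevelClustering:
    """Cluster cells at each of ``n_levels`` ascending density thresholds.

    Thresholds are ``t_0 = 0+`` plus ``t_k = k * max(cell_density) /
    n_levels`` for k = 1..n_levels-1 (``spacing="quantile"`` instead places
    them at equal quantiles of the positive cell densities).  At each
    threshold DBSCAN(eps, min_samples) runs on the coordinates of the cells
    at or above it.
    """
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    if list(embedding.index) != density.cell_ids:
        raise ValidationError("embedding cells do not match the density model")
    dens = density.cell_density
    dmax = dens.max()
    if spacing == "linear":
        thresholds = np.concatenate(
            [[np.finfo(float).tiny],
             np.arange(1, n_levels) * dmax / n_levels])
    elif spacing == "quantile":
        qs = np.linspace(0, 1, n_levels, endpoint=False)
        thresholds = np.quantile(dens[dens > 0], qs)
        thresholds[0] = np.finfo(float).tiny
    else:
        raise ValidationError(f"unknown spacing {spacing!r}")

    if eps is None:
        eps = default_eps(embedding)
    coords = embedding[["x", "y"]].values
    labels: list[np.ndarray] = []
    for k, t in enumerate(thresholds):
        mask = dens >= t
        lab = np.full(len(coords), -2, dtype=int)
        if mask.sum() < min_samples:
            logger.warning("level %d: only %d cells above threshold; skipped",
                           k, int(mask.sum()))
        else:
            lab[mask] = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
                coords[mask])
        labels.append(lab)
    return SuperlevelClustering(thresholds=thresholds, labels=labels,
                                eps=float(eps), min_samples=min_samples,
                                cell_ids=density.cell_ids)


# ---------------------------------------------------------------------------
# peak selection

@dataclass
class Peak:
    peak_id: str
    level: int
    cells: list[str]
    centroid: tuple[float, float]
    anchor_gene: str | None = None

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class PeakSet:
    peaks: list[Peak]
    membership: pd.Series          # cell -> peak_id for cells inside a peak
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"peak_id": p.peak_id, "level": p.level, "n_cells": len(p),
              "x": p.centroid[0], "y": p.centroid[1],
              "anchor_gene": p.anchor_gene} for p in self.peaks]
        ).set_index("peak_id")


def select_peaks(levels: SuperlevelClustering, embedding: pd.DataFrame,
                 min_cells: int = 20) -> PeakSet:
    """Innermost superlevel clusters = peaks.

    Only *qualifying* clusters (>= ``min_cells`` members) are considered.
    A qualifying cluster at level k is a peak iff no qualifying cluster at
    the next higher populated level has the majority (> 50%) of its cells
    inside it.  Cells belonging to several selected peaks are assigned to
    the highest-level one.
    """
    coords = embedding[["x", "y"]].values
    cells = np.array(levels.cell_ids)
    # qualifying clusters per level: list of (level, cluster_label, index set)
    per_level: list[list[set[int]]] = []
    for lab in levels.labels:
        clusters = []
        for cl in np.unique(lab[lab >= 0]):
            idx = set(np.flatnonzero(lab == cl))
            if len(idx) >= min_cells:
                clusters.append(idx)
        per_level.append(clusters)

    selected: list[tuple[int, set[int]]] = []
    for k, clusters in enumerate(per_level):
        # next higher level that has any qualifying cluster
        child_levels = [c for lvl in per_level[k + 1:k + 2] for c in lvl]
        for idx in clusters:
            has_nested_child = any(
                len(child & idx) > 0.5 * len(child) for child in child_levels)
            if not has_nested_child:
                selected.append((k, idx))
    if not selected:
        raise ValidationError("no peaks at current settings "
                              f"(min_cells={min_cells})")

    # resolve overlaps: each cell goes to its highest-level containing peak
    selected.sort(key=lambda t: (t[0], -len(t[1])))
    owner = {}
    for rank, (k, idx) in enumerate(selected):
        for i in idx:
            prev = owner.get(i)
            if prev is None or selected[prev][0] < k:
                owner[i] = rank

    peaks: list[Peak] = []
    membership = {}
    kept = sorted(set(owner.values()),
                  key=lambda r: (-len(selected[r][1]), selected[r][0]))
    for new_id, rank in enumerate(kept):
        k, idx = selected[rank]
        members = sorted(i for i, r in owner.items() if r == rank)
        if len(members) < min_cells:
            continue
        pid = f"peak_{new_id}"
        pts = coords[members]
        peaks.append(Peak(peak_id=pid, level=k,
                          cells=[str(c) for c in cells[members]],
                          centroid=(float(pts[:, 0].mean()),
                                    float(pts[:, 1].mean()))))
        for i in members:
            membership[str(cells[i])] = pid
    if not peaks:
        raise ValidationError("no peaks at current settings "
                              f"(min_cells={min_cells})")
    return PeakSet(peaks=peaks,
                   membership=pd.Series(membership, name="peak_id"),
                   params={"min_cells": min_cells, "eps": levels.eps,
                           "min_samples": levels.min_samples})


def anchor_gene(peak: Peak, expr: pd.DataFrame,
                priority: PriorityGeneSet) -> str | None:
    """Priority gene with the highest mean expression over the peak's cells
    (ties broken by higher RTS, then gene id); None when nothing is
    expressed."""
    if len(peak) == 0:
        raise ValidationError("peak has no member cells")
    genes = [g for g in priority.genes if g in expr.index]
    means = expr.loc[genes, peak.cells].mean(axis=1)
    if (means <= 0).all():
        logger.warning("peak %s expresses no priority gene", peak.peak_id)
        return None
    rts = priority.rts.loc[genes].values
    order = np.lexsort((np.array(genes), -rts, -means.values))
    return str(np.array(genes)[order][0])


def annotate_anchor_genes(peakset: PeakSet, expr: pd.DataFrame,
                          priority: PriorityGeneSet) -> PeakSet:
    for p in peakset.peaks:
        p.anchor_gene = anchor_gene(p, expr, priority)
    return peakset


# ---------------------------------------------------------------------------
# Jaccard dendrogram over peaks

def jaccard_similarity(lists: dict[str, pd.Series | list]) -> pd.DataFrame:
    """Pairwise Jaccard similarity of the top-gene lists of each peak."""
    if len(lists) < 2:
        raise ValidationError("need at least 2 peaks")
    sets = {}
    for pid, genes in lists.items():
        ids = list(genes.index) if isinstance(genes, pd.Series) else list(genes)
        if not ids:
            raise ValidationError(f"empty gene list for peak {pid!r}")
        sets[pid] = set(ids)
    pids = list(sets)
    mat = pd.DataFrame(np.eye(len(pids)), index=pids, columns=pids)
    for i, p in enumerate(pids):
        for q in pids[i + 1:]:
            j = len(sets[p] & sets[q]) / len(sets[p] | sets[q])
            mat.loc[p, q] = mat.loc[q, p] = j
    return mat


@dataclass
class PeakDendrogram:
    similarity: pd.DataFrame
    linkage: np.ndarray
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.similarity.index[i]
                for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.similarity.index)

        def rec(node):
            if node.is_leaf():
                return names[node.id]
            return (f"({rec(node.get_left())},{rec(node.get_right())})"
                    f":{node.dist:.6g}")

        return rec(tree) + ";"


def peak_dendrogram(similarity: pd.DataFrame,
                    method: str = "complete") -> PeakDendrogram:
    """Hierarchical tree over peaks from Euclidean distances between the
    rows of the Jaccard similarity matrix."""
    if method not in ("complete", "average", "ward"):
        raise ValidationError(f"unsupported linkage {method!r}")
    vals = similarity.values
    if np.isnan(vals).any():
        raise ValidationError("similarity matrix contains NaN")
    if not np.allclose(vals, vals.T):
        raise ValidationError("similarity matrix must be symmetric")
    dist = pdist(vals, metric="euclidean")
    link = hierarchy.linkage(dist, method=method)
    return PeakDendrogram(similarity=similarity, linkage=link, method=method)
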