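"""Model/Results front end for the two analyses.

`TriageCluster` fits the RTS-weighted density model to an expression matrix
plus 2D embedding and returns a results object carrying the peak calls;
`TriageParse` fits the pattern-based gene-grouping model to a breadth
matrix plus ranked gene list.  Both follow the fit()/Results convention:
the model object holds data and tunables, fit() does the work, and the
results object carries estimates, diagnostics and a summary() table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cluster as _cluster
from . import discordance as _ds
from . import parse as _parse
from .errors import ValidationError
from .rts import PriorityGeneSet, select_priority_genes


class TriageCluster:
    """Cell-population peak model over a 2D embedding.

    Parameters
    ----------
    expr : DataFrame (genes x cells)
        Normalised expression; cells must match the embedding.
    embedding : DataFrame (cells x 2)
        Precomputed 2D coordinates (e.g. UMAP), columns x/y.
    priority : PriorityGeneSet, or rts_table + selection settings
        The weighting gene set.  Pass either a ready `priority` or an
        `rts_table` (the priority set is then selected by the inflection
        method, or `fixed_threshold` when given).
    bandwidth : float, optional
        KDE bandwidth; default ``0.3 * n ** (-1/6)``.
    """

    def __init__(self, expr: pd.DataFrame, embedding: pd.DataFrame,
                 priority: PriorityGeneSet | None = None,
                 rts_table: pd.DataFrame | None = None,
                 fixed_threshold: float | None = None,
                 bandwidth: float | None = None, n_levels: int = 10,
                 eps: float | None = None, min_samples: int = 5,
                 min_cells: int = 20, spacing: str = "linear"):
        if set(expr.columns) != set(embedding.index):
            raise ValidationError("expression cells and embedding cells differ")
        self.expr = expr
        self.embedding = embedding.loc[expr.columns]
        if priority is None:
            if rts_table is None:
                raise ValidationError("need priority or rts_table")
            method = "fixed" if fixed_threshold is not None else "inflection"
            priority = select_priority_genes(rts_table, method=method,
                                             fixed_threshold=fixed_threshold)
        self.priority = priority
        self.bandwidth = bandwidth
        self.n_levels = n_levels
        self.eps = eps
        self.min_samples = min_samples
        self.min_cells = min_cells
        self.spacing = spacing

    def fit(self) -> "TriageClusterResults":
        h = self.bandwidth
        if h is None:
            h = _cluster.kde_bandwidth(len(self.embedding), 2)
        weights = _cluster.assign_cell_weights(self.expr, self.priority)
        density = _cluster.weighted_kde(self.embedding, weights, h)
        levels = _cluster.superlevel_clusters(
            density, self.embedding, n_levels=self.n_levels, eps=self.eps,
            min_samples=self.min_samples, spacing=self.spacing)
        peaks = _cluster.select_peaks(levels, self.embedding,
                                      min_cells=self.min_cells)
        _cluster.annotate_anchor_genes(peaks, self.expr, self.priority)
        return TriageClusterResults(model=self, weights=weights,
                                    density=density, levels=levels,
                                    peaks=peaks, bandwidth=h)


@dataclass
class TriageClusterResults:
    """Peak calls plus the fitted density and per-level clusterings."""

    model: TriageCluster
    weights: pd.DataFrame
    density: _cluster.DensityModel
    levels: _cluster.SuperlevelClustering
    peaks: _cluster.PeakSet
    bandwidth: float

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def membership(self) -> pd.Series:
        return self.peaks.membership

    def peak_table(self) -> pd.DataFrame:
        return self.peaks.table()

    def pseudo_bulk_rankings(self, rts, top_n: int = 100) -> dict[str, pd.Series]:
        return _ds.pseudo_bulk_ds(self.model.expr, self.membership, rts,
                                  top_n=top_n)

    def jaccard_dendrogram(self, rts, top_n: int = 100,
                           linkage: str = "complete"):
        lists = self.pseudo_bulk_rankings(rts, top_n=top_n)
        sim = _cluster.jaccard_similarity(lists)
        return _cluster.peak_dendrogram(sim, method=linkage)

    def summary(self) -> str:
        tab = self.peak_table()
        lines = [
            "TRIAGE-Cluster results",
            "======================",
            f"cells:          {self.density.n}",
            f"priority genes: {len(self.model.priority)}",
            f"bandwidth:      {self.bandwidth:.4g}",
            f"contour levels: {self.model.n_levels}"
            f" (eps={self.levels.eps:.4g},"
            f" min_samples={self.levels.min_samples})",
            f"peaks:          {self.n_peaks}"
            f" covering {int(tab['n_cells'].sum())} cells",
            "",
            tab.to_string(),
        ]
        return "\n".join(lines)

    def plot_density(self, ax=None, n_grid: int = 200, levels: int = 10):
        """Contour plot of the fitted density with peak centroids."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs, ys, z = self.density.grid(n_grid=n_grid)
        ax.contour(xs, ys, z, levels=levels, cmap="viridis")
        pts = self.model.embedding
        ax.scatter(pts["x"], pts["y"], s=2, c="0.8", zorder=0)
        tab = self.peak_table()
        ax.scatter(tab["x"], tab["y"], marker="x", c="red")
        for pid, row in tab.iterrows():
            ax.annotate(str(pid), (row["x"], row["y"]), fontsize=7)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        return ax


class TriageParse:
    """Pattern-based grouping model for a ranked gene list.

    Parameters
    ----------
    breadth : DataFrame (genes x samples), optional
        H3K27me3 breadth matrix defining the pattern space; alternatively
        pass a fitted ``pc_model``.
    gene_list : ordered gene identifiers
        The list to partition (typically a top-100 DS ranking).
    n_pcs : int
        PCs retained from the breadth PCA (required with `breadth`).
    m : int
        PCs kept as GMM features after ranking by gene-set variance.
    """

    def __init__(self, gene_list, breadth: pd.DataFrame | None = None,
                 pc_model: _parse.PCModel | None = None,
                 n_pcs: int | None = None, m: int = 10, theta_max: int = 100,
                 repeats: int = 10, seed: int = 42, tol: float = 1e-3,
                 bic_mode: str = "standard", n_perm: int = 1000):
        if pc_model is None:
            if breadth is None or n_pcs is None:
                raise ValidationError("need breadth + n_pcs, or pc_model")
            pc_model = _parse.fit_h3k27me3_pca(breadth, n_pcs)
        self.pc_model = pc_model
        self.gene_list = list(gene_list)
        self.m = m
        self.theta_max = min(theta_max, len(self.gene_list))
        self.repeats = repeats
        self.seed = seed
        self.tol = tol
        self.bic_mode = bic_mode
        self.n_perm = n_perm

    def fit(self, run_enrichment: bool = True) -> "TriageParseResults":
        pcs = _parse.rank_pcs_by_gene_set_variance(self.pc_model,
                                                   self.gene_list, m=self.m)
        features = self.pc_model.scores.loc[self.gene_list, pcs]
        scan = _parse.scan_cluster_number(
            features, theta_max=self.theta_max, repeats=self.repeats,
            seed=self.seed, tol=self.tol, bic_mode=self.bic_mode)
        gmm = _parse.assign_gene_clusters(features, scan.theta_star,
                                          seed=self.seed, tol=self.tol)
        enrichment = None
        if run_enrichment:
            enrichment = _parse.pattern_enrichment(
                self.pc_model, self.gene_list, n_perm=self.n_perm,
                seed=self.seed)
        return TriageParseResults(model=self, selected_pcs=pcs,
                                  features=features, scan=scan, gmm=gmm,
                                  enrichment=enrichment)


@dataclass
class TriageParseResults:
    model: TriageParse
    selected_pcs: list[str]
    features: pd.DataFrame
    scan: _parse.BICScan
    gmm: _parse.GeneClusterModel
    enrichment: _parse.EnrichmentResult | None = None

    @property
    def theta_star(self) -> int:
        return self.scan.theta_star

    @property
    def assignments(self) -> pd.Series:
        return self.gmm.assignments

    def cluster_table(self) -> pd.DataFrame:
        post = self.gmm.posteriors.max(axis=1)
        return pd.DataFrame({"cluster": self.gmm.assignments,
                             "posterior": post})

    def summary(self) -> str:
        sizes = self.gmm.assignments.value_counts().sort_index()
        lines = [
            "TRIAGE-ParseR results",
            "=====================",
            f"genes:        {len(self.model.gene_list)}",
            f"selected PCs: {', '.join(self.selected_pcs)}",
            f"theta* (BIC): {self.theta_star}"
            f"  [per-repeat argmins: {self.scan.theta_per_repeat}]",
            "cluster sizes:",
            sizes.to_string(),
        ]
        if self.enrichment is not None:
            n_strong = int(self.enrichment.strong.values.any(axis=1).sum())
            lines.append(f"genes strongly associated with >=1 pattern: "
                         f"{n_strong}")
        return "\n".join(lines)
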