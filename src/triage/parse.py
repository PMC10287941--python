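"""Grouping a ranked gene list by its H3K27me3 deposition patterns.

PCA of the gene x bio-sample H3K27me3 breadth matrix (genes are the
observations, samples the variables) extracts orthogonal deposition
patterns.  An input gene list — typically the top 100 genes of a pseudo-bulk
DS ranking — is then examined in that PC space: per-gene permutation tests
flag strong associations with individual patterns, the PCs with the highest
variance among the input genes are kept as features, a BIC scan over a
diagonal-covariance Gaussian mixture selects the number of gene clusters,
and each gene is assigned to the cluster with the highest posterior
probability.
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .errors import ValidationError

logger = logging.getLogger("triage")


# ---------------------------------------------------------------------------
# PCA of breadth

@dataclass
class PCModel:
    scores: pd.DataFrame               # genes x PCs
    loadings: pd.DataFrame             # samples x PCs
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray                  # per-sample column means

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


def fit_h3k27me3_pca(breadth: pd.DataFrame, n_pcs: int) -> PCModel:
    """PCA of the breadth matrix with genes as observations.

    Columns (samples) are mean-centred, not variance-scaled.  Raises when
    ``n_pcs`` exceeds the matrix rank.
    """
    if breadth.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    max_rank = min(breadth.shape[0] - 1, breadth.shape[1])
    if n_pcs > max_rank:
        raise ValidationError(
            f"n_pcs={n_pcs} exceeds the matrix rank bound {max_rank}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(breadth.values.astype(float))
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return PCModel(
        scores=pd.DataFrame(scores, index=breadth.index, columns=cols),
        loadings=pd.DataFrame(pca.components_.T, index=breadth.columns,
                              columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_=pca.mean_,
    )


# ---------------------------------------------------------------------------
# permutation enrichment of patterns

@dataclass
class EnrichmentResult:
    """Per gene x PC permutation enrichment.

    ``exceed_count`` holds r_i, the number of permutations whose null
    statistic was at least the observed score; ``p = (r_i + 1)/(n_perm + 1)``.
    ``strong`` flags genes whose score exceeds the 95th percentile of the
    universe on that PC.
    """

    exceed_count: pd.DataFrame
    p: pd.DataFrame
    strong: pd.DataFrame
    n_perm: int


def pattern_enrichment(pc_model: PCModel, gene_set, n_perm: int = 1000,
                       seed: int = 0, statistic: str = "quantile",
                       quantile: float = 0.95) -> EnrichmentResult:
    """Permutation test of each input gene's association with each pattern.

    For every permutation a random gene set of the same size is drawn from
    the universe (all genes in the PC model, excluding the input set — the
    null is "another" gene set).  The null statistic per PC is
    the 95th percentile of the sampled genes' scores
    (``statistic="quantile"``) or their maximum (``statistic="max"``); r_i
    counts permutations whose statistic reached the observed gene score, and
    ``p_i = (r_i + 1)/(n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if statistic not in ("quantile", "max"):
        raise ValidationError("statistic must be 'quantile' or 'max'")
    gene_set = list(gene_set)
    universe = pc_model.scores.index
    missing = [g for g in gene_set if g not in universe]
    if missing:
        raise ValidationError(f"gene not in universe: {missing[0]!r}")

    scores = pc_model.scores
    obs = scores.loc[gene_set].values                    # (S, P)
    cutoffs = np.quantile(scores.values, quantile, axis=0)
    strong = obs > cutoffs[None, :]

    rng = np.random.default_rng(seed)
    r = np.zeros(obs.shape, dtype=int)
    in_set = universe.isin(gene_set)
    pool = np.flatnonzero(~in_set)
    if pool.size < len(gene_set):
        raise ValidationError("universe too small for a disjoint null sample")
    vals = scores.values
    for _ in range(n_perm):
        idx = rng.choice(pool, size=len(gene_set), replace=False)
        sample = vals[idx]
        if statistic == "quantile":
            stat = np.quantile(sample, quantile, axis=0)
        else:
            stat = sample.max(axis=0)
        r += stat[None, :] >= obs
    p = (r + 1) / (n_perm + 1)
    cols = scores.columns
    return EnrichmentResult(
        exceed_count=pd.DataFrame(r, index=gene_set, columns=cols),
        p=pd.DataFrame(p, index=gene_set, columns=cols),
        strong=pd.DataFrame(strong, index=gene_set, columns=cols),
        n_perm=n_perm,
    )


def rank_pcs_by_gene_set_variance(pc_model: PCModel, gene_set,
                                  m: int = 10) -> list[str]:
    """The m PCs with the largest score variance among the input gene set."""
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValidationError("gene_set must contain at least 2 genes")
    if m > pc_model.n_pcs:
        raise ValidationError(f"m={m} exceeds retained PCs ({pc_model.n_pcs})")
    sub = pc_model.scores.loc[gene_set]
    var = sub.var(axis=0, ddof=1)
    order = np.lexsort((np.arange(len(var)), -var.values))
    return [var.index[i] for i in order[:m]]


# ---------------------------------------------------------------------------
# BIC scan for the cluster number

@dataclass
class BICScan:
    """Per-repeat BIC curves over candidate cluster numbers.

    ``bic`` is a (repeats x theta_max) DataFrame (NaN where a fit was
    degenerate or failed); ``theta_per_repeat`` the argmin per repeat;
    ``theta_star`` the most frequent argmin (ties toward smaller theta).
    """

    bic: pd.DataFrame
    theta_per_repeat: list[int]
    theta_star: int
    bic_mode: str
    params: dict = field(default_factory=dict)


def _bic_value(gm: GaussianMixture, X: np.ndarray, mode: str) -> float:
    n, d = X.shape
    theta = gm.n_components
    mean_lnL = gm.score(X)
    if mode == "mean":
        return theta * np.log(n) - 2.0 * mean_lnL
    if mode == "total":
        return theta * np.log(n) - 2.0 * mean_lnL * n
    if mode == "standard":
        k_params = theta * (2 * d + 1) - 1
        return k_params * np.log(n) - 2.0 * mean_lnL * n
    raise ValidationError(f"unknown bic_mode {mode!r}")


def _fit_gmm(X: np.ndarray, theta: int, seed: int, tol: float,
             reg_covar: float = 1e-6) -> GaussianMixture:
    gm = GaussianMixture(n_components=theta, covariance_type="diag",
                         tol=tol, reg_covar=reg_covar, init_params="random",
                         random_state=seed, max_iter=200)
    gm.fit(X)
    return gm


def scan_cluster_number(features: pd.DataFrame, theta_max: int = 100,
                        repeats: int = 10, seed: int = 42, tol: float = 1e-3,
                        bic_mode: str = "standard") -> BICScan:
    """Select the gene-cluster number by a BIC scan over GMM fits.

    For each candidate theta a diagonal-covariance Gaussian mixture is fit
    by EM (randomly initialised, convergence when the log-likelihood gain
    drops below ``tol``) and its BIC recorded; the most frequent per-repeat
    argmin over ``repeats`` scans wins, ties going to the smaller theta.

    ``bic_mode`` picks the penalty.  "standard" (default) is the textbook
    criterion ``k_params * ln(n) - 2 * ln(L)`` with k_params the free
    parameters of a theta-component diagonal GMM; it is the only variant
    that is well behaved when theta ranges up to n, because the mixture
    likelihood is unbounded and per-cluster penalties cannot hold back
    overfitting.  "total" applies the cluster-count penalty
    ``theta * ln(n)`` to the total log-likelihood; "mean" applies it to the
    mean per-gene log-likelihood.  Degenerate fits (a component variance at
    the regularisation floor) are excluded from the argmin; EM failures are
    skipped with a warning, never silently.  Counts of both are recorded in
    ``params``.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if theta_max > n:
        raise ValidationError(f"theta_max={theta_max} exceeds n={n}")
    if theta_max < 1:
        raise ValidationError("theta_max must be >= 1")
    rng = np.random.default_rng(seed)
    bic = np.full((repeats, theta_max), np.nan)
    winners: list[int] = []
    n_degenerate = n_failed = 0
    for rep in range(repeats):
        for theta in range(1, theta_max + 1):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            try:
                gm = _fit_gmm(X, theta, sub_seed, tol)
            except Exception as exc:   # EM failure: skip, never silently
                n_failed += 1
                logger.warning("EM failed at theta=%d (repeat %d): %s",
                               theta, rep, exc)
                continue
            if gm.covariances_.min() <= 1e-5:
                n_degenerate += 1
                logger.debug("degenerate fit at theta=%d (repeat %d): "
                             "variance at floor; excluded", theta, rep)
                continue
            bic[rep, theta - 1] = _bic_value(gm, X, bic_mode)
        row = bic[rep]
        if np.isnan(row).all():
            logger.warning("repeat %d produced no valid fit", rep)
            continue
        winners.append(int(np.nanargmin(row)) + 1)
    if not winners:
        raise ValidationError("BIC scan produced no valid fit at any theta")
    counts = collections.Counter(winners)
    best = max(counts.values())
    theta_star = min(t for t, c in counts.items() if c == best)
    return BICScan(
        bic=pd.DataFrame(bic, columns=range(1, theta_max + 1)),
        theta_per_repeat=winners,
        theta_star=theta_star,
        bic_mode=bic_mode,
        params={"repeats": repeats, "seed": seed, "tol": tol,
                "theta_max": theta_max, "n_degenerate": n_degenerate,
                "n_failed": n_failed},
    )


# ---------------------------------------------------------------------------
# posterior assignment

@dataclass
class GeneClusterModel:
    assignments: pd.Series             # gene -> cluster id (0-based)
    posteriors: pd.DataFrame           # genes x clusters
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    theta: int
    seed: int


def assign_gene_clusters(features: pd.DataFrame, theta_star: int,
                         seed: int = 42, tol: float = 1e-3,
                         max_refits: int = 10) -> GeneClusterModel:
    """Fit the final GMM and assign each gene to its argmax-posterior
    cluster.  An empty component after convergence triggers a logged refit
    with a new derived seed."""
    if theta_star < 1:
        raise ValidationError("theta_star must be >= 1")
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    gm = None
    for attempt in range(max_refits):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cand = _fit_gmm(X, theta_star, sub_seed, tol)
        resp = cand.predict_proba(X)
        occupied = (resp.argmax(axis=1)[:, None] ==
                    np.arange(theta_star)[None, :]).any(axis=0)
        if occupied.all():
            gm = cand
            break
        logger.warning("empty component after convergence (attempt %d); "
                       "refitting with a new seed", attempt)
    if gm is None:
        gm = cand
        logger.warning("empty component persisted after %d refits", max_refits)
    post = gm.predict_proba(X)
    idx = features.index if hasattr(features, "index") else range(len(X))
    return GeneClusterModel(
        assignments=pd.Series(post.argmax(axis=1), index=idx, name="cluster"),
        posteriors=pd.DataFrame(post, index=idx,
                                columns=range(theta_star)),
        weights=gm.weights_,
        means=gm.means_,
        variances=gm.covariances_,
        theta=theta_star,
        seed=seed,
    )
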