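"""Benchmarking statistics: ARI, gene-removal ablations, peak-peak
Spearman correlation, highly variable gene selection and rank-bin Fisher
enrichment."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cluster import assign_cell_weights
from .errors import ValidationError
from .rts import PriorityGeneSet

logger = logging.getLogger("triage")

ABLATION_SCENARIOS = ("random_priority", "bottom_up", "top_down",
                      "random_genome")


def adjusted_rand_index(a: pd.Series, b: pd.Series) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a, b = pd.Series(a), pd.Series(b)
    if set(a.index) != set(b.index):
        raise ValidationError("partitions cover different item sets")
    b = b.reindex(a.index)
    return float(adjusted_rand_score(a.astype(str).values,
                                     b.astype(str).values))


def _anchor_labels(expr: pd.DataFrame, priority: PriorityGeneSet,
                   keep: set[str]) -> pd.Series:
    genes = [g for g in priority.genes if g in keep and g in expr.index]
    if not genes:
        return pd.Series("none", index=expr.columns)
    sub = PriorityGeneSet(genes=genes, rts=priority.rts.loc[genes],
                          threshold=priority.threshold,
                          method=priority.method)
    w = assign_cell_weights(expr, sub)
    return w["anchor_candidate"].fillna("none").astype(str)


def gene_removal_experiment(expr: pd.DataFrame, priority: PriorityGeneSet,
                            scenario: str, step: int = 50,
                            seed: int = 0) -> pd.DataFrame:
    """ARI degradation under cumulative gene removal.

    The gold standard labels each cell by its highest-expressed priority
    gene computed from the full priority list.  Genes are then removed
    cumulatively in blocks of ``step`` following the scenario — random
    draws from the priority list, bottom-to-top or top-to-bottom of the RTS
    ranking, or random draws from the whole gene universe — and after each
    block the labelling is recomputed from the surviving genes and compared
    to gold by ARI.  A step that leaves no priority gene reports ARI = 0
    with ``total_removal = True``.
    """
    if scenario not in ABLATION_SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}; "
                              f"choose from {ABLATION_SCENARIOS}")
    if len(priority) == 0:
        raise ValidationError("priority gene set is empty")
    rng = np.random.default_rng(seed)
    gold = _anchor_labels(expr, priority, set(priority.genes))

    if scenario == "random_priority":
        pool = list(priority.genes)
        rng.shuffle(pool)
    elif scenario == "top_down":
        pool = list(priority.genes)                  # already rts-descending
    elif scenario == "bottom_up":
        pool = list(priority.genes)[::-1]
    else:                                            # random_genome
        pool = list(expr.index)
        rng.shuffle(pool)

    n_steps = len(pool) // step
    rows = []
    removed: set[str] = set()
    for s in range(1, n_steps + 1):
        removed.update(pool[(s - 1) * step: s * step])
        keep = set(priority.genes) - removed
        if not keep:
            rows.append({"step": s, "n_removed": len(removed),
                         "ari": 0.0, "total_removal": True})
            continue
        labels = _anchor_labels(expr, priority, keep)
        rows.append({"step": s, "n_removed": len(removed),
                     "ari": adjusted_rand_index(gold, labels),
                     "total_removal": False})
    out = pd.DataFrame(rows)
    out.insert(0, "scenario", scenario)
    return out


def spearman_peak_correlation(profiles: pd.DataFrame,
                              gene_subset="all",
                              n_hvg: int = 1000) -> pd.DataFrame:
    """Pairwise Spearman correlation between per-peak gene profiles.

    ``profiles`` is genes x peaks (e.g. pseudo-bulk mean expression or DS).
    ``gene_subset`` may be "all", "hvg" (top ``n_hvg`` highly variable rows
    of the profile matrix) or an explicit gene list.  Constant profiles
    yield NaN entries with a warning.
    """
    if profiles.shape[1] < 2:
        raise ValidationError("need at least 2 peaks")
    if isinstance(gene_subset, str):
        if gene_subset == "hvg":
            genes = select_hvg(profiles, n=min(n_hvg, profiles.shape[0]))
        elif gene_subset == "all":
            genes = list(profiles.index)
        else:
            raise ValidationError(f"unknown gene_subset {gene_subset!r}")
    else:
        genes = list(gene_subset)
    sub = profiles.loc[genes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = sub.corr(method="spearman")
        # constant profiles: pandas leaves 1 on the diagonal but the
        # pairwise coefficient is undefined
        const = sub.nunique(axis=0) <= 1
        out.loc[const, :] = np.nan
        out.loc[:, const] = np.nan
    if out.isna().values.any():
        logger.warning("constant profile: undefined correlations set to NaN")
    return out


def select_hvg(expr: pd.DataFrame, n: int = 1000) -> list[str]:
    """Top-n highly variable genes by residual from a mean-variance trend.

    A LOWESS local regression of log variance on log mean is fitted across
    genes; genes are ranked by their residual (observed minus trend) and
    the top n returned, ties broken by gene id.  Degenerate input (all
    genes identically distributed) is flagged with a warning.
    """
    if n > expr.shape[0]:
        raise ValidationError(f"n={n} exceeds the {expr.shape[0]} genes")
    mean = expr.mean(axis=1).values
    var = expr.var(axis=1, ddof=1).values
    log_mean = np.log1p(mean)
    log_var = np.log1p(var)
    if np.allclose(log_var, log_var[0]) or np.allclose(log_mean, log_mean[0]):
        logger.warning("degenerate mean-variance structure; "
                       "selection is a tie-broken subset")
        resid = log_var
    else:
        trend = lowess(log_var, log_mean, frac=0.3, return_sorted=False)
        resid = log_var - trend
    order = np.lexsort((expr.index.values, -resid))
    return list(expr.index.values[order][:n])


def rank_bin_enrichment(ranking: pd.Series, target_set,
                        n_bins: int = 10) -> pd.DataFrame:
    """Per-rank-bin enrichment of a target gene set (one-tailed Fisher).

    The ranked genes are split into ``n_bins`` contiguous bins; each bin is
    tested against all ranked genes with the 2x2 table (in-bin targets,
    in-bin non-targets, out-bin targets, out-bin non-targets) and the
    one-tailed (greater) Fisher's exact test.
    """
    genes = list(ranking.index)
    targets = set(target_set)
    stray = targets - set(genes)
    if stray:
        raise ValidationError(f"target gene not in ranking: {sorted(stray)[:5]}")
    edges = np.linspace(0, len(genes), n_bins + 1).round().astype(int)
    rows = []
    for b in range(n_bins):
        members = genes[edges[b]:edges[b + 1]]
        if not members:
            raise ValidationError(f"bin {b} is empty")
        in_t = sum(g in targets for g in members)
        in_n = len(members) - in_t
        out_t = len(targets) - in_t
        out_n = len(genes) - len(members) - out_t
        odds, p = scipy.stats.fisher_exact([[in_t, in_n], [out_t, out_n]],
                                           alternative="greater")
        rows.append({"bin": b + 1, "n_genes": len(members),
                     "n_targets": in_t, "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows).set_index("bin")
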