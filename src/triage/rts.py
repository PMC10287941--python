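"""Repressive tendency scoring from H3K27me3 breadth.

Broad H3K27me3 domains mark developmentally regulated loci.  For every gene
we measure the breadth (bp) of domains overlapping a window around its TSS
in each bio-sample, then combine (i) the summed breadth across samples,
min-max scaled to [0, 1], with (ii) the fraction of samples in which the
gene's breadth falls in the top tail (default 5%) of that sample's broad
domains.  The product is the repressive tendency score (RTS); genes above
the inflection point of the sorted RTS curve form the priority set used for
cell weighting and peak anchoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

logger = logging.getLogger("triage")


def compute_gene_breadth(intervals_by_sample: dict[str, pd.DataFrame],
                         gene_models: pd.DataFrame,
                         window_halfwidth: int = 2500,
                         mode: str = "broadest") -> pd.DataFrame:
    """Per-gene, per-sample H3K27me3 breadth at TSS-proximal windows.

    A domain counts for a gene when it overlaps ``[tss - w, tss + w + 1)``.
    ``mode="broadest"`` records the full length of the broadest overlapping
    domain (if several overlap, the broadest is chosen); ``mode="total"``
    sums the lengths of all overlapping domains.  Genes with no overlapping
    domain score 0.

    Returns an int DataFrame of shape (genes, samples).
    """
    if mode not in ("broadest", "total"):
        raise ValidationError(f"mode must be 'broadest' or 'total', got {mode!r}")
    if len(gene_models) == 0:
        raise ValidationError("empty gene set")
    if window_halfwidth < 0:
        raise ValidationError("window_halfwidth must be >= 0")

    genes = gene_models.index
    out = pd.DataFrame(0, index=genes, columns=list(intervals_by_sample),
                       dtype=int)
    win_lo = np.maximum(gene_models["tss"].values - window_halfwidth, 0)
    win_hi = gene_models["tss"].values + window_halfwidth + 1

    any_hit = False
    for sample, iv in intervals_by_sample.items():
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in iv.groupby("chrom", sort=False):
            trees[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"]))
        col = np.zeros(len(genes), dtype=int)
        for i, (chrom, lo, hi) in enumerate(
                zip(gene_models["chrom"].values, win_lo, win_hi)):
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = tree.overlap(lo, hi)
            if not hits:
                continue
            lengths = [h.end - h.begin for h in hits]
            col[i] = max(lengths) if mode == "broadest" else sum(lengths)
        if col.any():
            any_hit = True
        out[sample] = col
    if not any_hit:
        logger.warning("no interval overlapped any gene window; "
                       "check chromosome naming")
    return out


def compute_rts(breadth: pd.DataFrame, top_fraction: float = 0.05) -> pd.DataFrame:
    """Repressive tendency score per gene.

    Per sample, the top ``ceil(top_fraction * G_nonzero)`` genes by breadth
    (among genes with breadth > 0; ties at the cut all included) are flagged
    as carrying a broad domain.  With ``v`` the flagged fraction over the N
    samples and ``a`` the summed breadth min-max scaled by the maximum gene,
    ``rts = a * v``, which lies in [0, 1].

    Returns a DataFrame with columns ``breadth_sum``, ``a``, ``v``, ``rts``
    sorted by descending rts (ties broken by gene_id).
    """
    if breadth.shape[1] < 2:
        raise ValidationError("need at least 2 samples to compute RTS")
    if not 0 < top_fraction < 1:
        raise ValidationError("top_fraction must lie in (0, 1)")
    vals = breadth.values.astype(float)
    if (vals < 0).any():
        raise ValidationError("breadth must be non-negative")
    if not vals.any():
        raise ValidationError("no H3K27me3 signal: breadth matrix is all zero")

    n_samples = breadth.shape[1]
    flags = np.zeros(breadth.shape, dtype=bool)
    for j in range(n_samples):
        col = vals[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            continue
        k = math.ceil(top_fraction * nonzero.size)
        cutoff = np.sort(nonzero)[::-1][k - 1]
        flags[:, j] = col >= cutoff  # inclusive ties at the cut

    breadth_sum = vals.sum(axis=1)
    a = breadth_sum / breadth_sum.max()
    v = flags.sum(axis=1) / n_samples
    table = pd.DataFrame(
        {"breadth_sum": breadth_sum, "a": a, "v": v, "rts": a * v},
        index=breadth.index,
    )
    table = table.sort_values(["rts"], ascending=False, kind="mergesort")
    # deterministic ordering: descending rts, then lexicographic gene_id
    table = table.iloc[
        np.lexsort((table.index.values, -table["rts"].values))
    ]
    return table


@dataclass
class PriorityGeneSet:
    """Ordered priority genes (descending RTS) above a threshold."""

    genes: list[str]
    rts: pd.Series                       # rts per priority gene, same order
    threshold: float
    method: str
    knee_rank: int | None = None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)


def _knee_rank(y: np.ndarray, smooth_window: int) -> int:
    """Index of maximum perpendicular distance from the chord of the curve."""
    x = np.arange(y.size, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[: y.size]
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0 or np.allclose(y, y[0]):
        raise ValidationError(
            "RTS curve is flat: no inflection point; use a fixed_threshold")
    # signed perpendicular distance of every point from the chord
    d = np.abs(chord[0] * (p0[1] - y) - chord[1] * (p0[0] - x)) / norm
    return int(np.argmax(d))


def select_priority_genes(rts_table: pd.DataFrame,
                          method: str = "inflection",
                          fixed_threshold: float | None = None,
                          min_nonzero: int = 100) -> PriorityGeneSet:
    """Select the priority gene set from an RTS table.

    ``method="inflection"`` sorts RTS descending, smooths the rank curve with
    a moving average (width 1% of genes, at least 11) and takes the knee as
    the point of maximum distance from the chord; genes strictly above the
    knee's RTS value are returned.  ``method="fixed"`` keeps genes with
    ``rts > fixed_threshold``.
    """
    order = np.lexsort((rts_table.index.values, -rts_table["rts"].values))
    table = rts_table.iloc[order]
    if method == "fixed":
        if fixed_threshold is None:
            raise ValidationError("method='fixed' requires fixed_threshold")
        threshold, knee = float(fixed_threshold), None
    elif method == "inflection":
        nz = int((table["rts"] > 0).sum())
        if nz < min_nonzero:
            raise ValidationError(
                f"inflection method needs >= {min_nonzero} genes with rts > 0 "
                f"(got {nz}); use method='fixed'")
        y = table["rts"].values.astype(float)
        window = max(11, int(round(0.01 * y.size)))
        knee = _knee_rank(y, window)
        if knee == 0 or knee == y.size - 1:
            raise ValidationError(
                "no interior knee on the RTS curve; use a fixed_threshold")
        threshold = float(table["rts"].values[knee])
    else:
        raise ValidationError(f"unknown method {method!r}")

    mask = table["rts"] > threshold
    genes = list(table.index[mask])
    if not genes:
        logger.warning("priority set is empty at threshold %g", threshold)
    return PriorityGeneSet(
        genes=genes,
        rts=table.loc[genes, "rts"],
        threshold=threshold,
        method=method,
        knee_rank=knee,
        params={"min_nonzero": min_nonzero},
    )
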