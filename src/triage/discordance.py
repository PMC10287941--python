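"""Discordance score (DS) transform and pseudo-bulk gene rankings.

DS multiplies log-transformed normalised expression with the gene's
repressive tendency score: ``ds(g, c) = ln(1 + expr(g, c)) * rts(g)``.
A high DS flags a gene that is expressed although usually repressed —
a candidate cell-identity regulator.  Genes missing from the RTS table are
treated as rts = 0 and can therefore never rank highly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("triage")


def _rts_series(rts) -> pd.Series:
    if isinstance(rts, pd.DataFrame):
        return rts["rts"]
    return pd.Series(rts)


def normalize_library_size(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell so its total equals the median cell total.

    Zero-total cells are dropped with a warning.  A simple library-size
    normalisation; deconvolution size factors are deliberately out of scope.
    """
    if (raw_counts.values < 0).any():
        raise ValidationError("raw counts must be non-negative")
    totals = raw_counts.sum(axis=0)
    zero = totals == 0
    if zero.all():
        raise ValidationError("all cells have zero total counts")
    if zero.any():
        logger.warning("dropping %d zero-total cell(s)", int(zero.sum()))
        raw_counts = raw_counts.loc[:, ~zero]
        totals = totals[~zero]
    median = float(totals.median())
    return raw_counts * (median / totals)


def discordance_transform(expr: pd.DataFrame, rts,
                          pseudocount: float = 1.0) -> pd.DataFrame:
    """DS matrix: ``ln(pseudocount + expr) * rts`` with ds=0 at expr=0.

    ``pseudocount`` is the additive offset inside the log; the default 1
    maps zero expression to ds = 0 exactly.
    """
    if (expr.values < 0).any():
        raise ValidationError("expression must be non-negative")
    r = _rts_series(rts).reindex(expr.index).fillna(0.0)
    ds = np.log(pseudocount + expr.values) * r.values[:, None]
    return pd.DataFrame(ds, index=expr.index, columns=expr.columns)


def rank_genes(ds: pd.Series, top_n: int | None = None) -> pd.Series:
    """Descending DS ranking with deterministic lexicographic tie-break."""
    order = np.lexsort((ds.index.values, -ds.values))
    ranked = ds.iloc[order]
    return ranked.head(top_n) if top_n is not None else ranked


def pseudo_bulk_ds(expr: pd.DataFrame, membership: pd.Series, rts,
                   top_n: int = 100,
                   average: str = "before") -> dict[str, pd.Series]:
    """Per-peak pseudo-bulk DS rankings.

    ``membership`` maps member cells to peak ids (cells outside any peak are
    simply absent).  For each peak the member cells' normalised expression
    is averaged, DS-transformed and ranked descending; the ``top_n`` genes
    are returned per peak.  ``average="after"`` instead averages per-cell DS
    values (exposed for comparison).
    """
    if average not in ("before", "after"):
        raise ValidationError("average must be 'before' or 'after'")
    membership = membership.dropna()
    missing = set(membership.index) - set(expr.columns)
    if missing:
        raise ValidationError(f"cells not in expression matrix: {sorted(missing)[:5]}")
    out: dict[str, pd.Series] = {}
    for peak, cells in membership.groupby(membership):
        ids = list(cells.index)
        if not ids:
            raise ValidationError(f"peak {peak!r} has no member cells")
        if average == "before":
            profile = expr[ids].mean(axis=1)
            ds = discordance_transform(profile.to_frame("p"), rts)["p"]
        else:
            ds = discordance_transform(expr[ids], rts).mean(axis=1)
        out[str(peak)] = rank_genes(ds, top_n)
    if not out:
        raise ValidationError("membership assigns no cell to any peak")
    return out
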