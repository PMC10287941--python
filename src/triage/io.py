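"""Readers and writers for the genomic formats the pipeline touches.

All genomic coordinates are 0-based, half-open internally.  GTF input
(1-based, closed) is converted on ingest.  Interval sets are represented as
:class:`pandas.DataFrame` objects with columns ``chrom``, ``start``, ``end``
and optionally ``score``; gene models as a DataFrame indexed by ``gene_id``
with columns ``chrom``, ``strand``, ``tss``; expression matrices as dense
gene x cell DataFrames; 2D embeddings as cell-indexed DataFrames with
columns ``x``, ``y``.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, ValidationError

logger = logging.getLogger("triage")

INTERVAL_FORMATS = ("bed", "broadpeak", "bedgraph")

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_BROADPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue",
]


def _infer_interval_format(path: str) -> str:
    ext = os.path.basename(path).lower()
    if ext.endswith(".broadpeak"):
        return "broadpeak"
    if ext.endswith(".bedgraph") or ext.endswith(".bdg"):
        return "bedgraph"
    return "bed"


def read_intervals(path: str, format: str | None = None) -> pd.DataFrame:
    """Read one BED / broadPeak / bedGraph file into an interval frame.

    Returns a DataFrame with columns ``chrom`` (str), ``start`` and ``end``
    (0-based half-open ints) and ``score`` (float, NaN when absent).
    Malformed lines raise :class:`ParseError` with the offending line number;
    ``end <= start`` raises :class:`ValidationError`.
    """
    fmt = (format or _infer_interval_format(path)).lower()
    if fmt not in INTERVAL_FORMATS:
        raise ValidationError(f"unknown interval format {fmt!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 tab-separated fields, got {len(fields)}",
                    path=path, line=lineno,
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}",
                                 path=path, line=lineno) from None
            if start < 0:
                raise ValidationError(
                    f"negative start {start} ({path}:{lineno})")
            if end <= start:
                raise ValidationError(
                    f"end {end} <= start {start} ({path}:{lineno})")
            score = np.nan
            if fmt == "bedgraph":
                if len(fields) < 4:
                    raise ParseError("bedGraph requires a 4th value column",
                                     path=path, line=lineno)
                score = float(fields[3])
            elif fmt == "broadpeak" and len(fields) >= 7:
                score = float(fields[6])
            elif fmt == "bed" and len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            rows.append((chrom, start, end, score))
    if not rows:
        logger.warning("interval file %s is empty", path)
        return pd.DataFrame(columns=["chrom", "start", "end", "score"]).astype(
            {"chrom": str, "start": int, "end": int, "score": float})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def read_interval_samples(source, format: str | None = None) -> dict[str, pd.DataFrame]:
    """Read a multi-sample interval collection.

    ``source`` may be a manifest TSV with columns ``sample_id`` and ``path``
    (header optional), a directory (every interval file inside becomes one
    sample, named by file stem), a glob pattern, or a mapping
    ``sample_id -> path``.
    """
    if isinstance(source, Mapping):
        items = list(source.items())
    elif os.path.isdir(source):
        paths = sorted(
            p for p in _glob.glob(os.path.join(source, "*"))
            if p.lower().endswith((".bed", ".broadpeak", ".bedgraph", ".bdg"))
        )
        items = [(os.path.splitext(os.path.basename(p))[0], p) for p in paths]
    elif any(ch in str(source) for ch in "*?["):
        paths = sorted(_glob.glob(str(source)))
        items = [(os.path.splitext(os.path.basename(p))[0], p) for p in paths]
    else:  # manifest TSV
        mf = pd.read_csv(source, sep="\t", comment="#", header=None,
                         names=["sample_id", "path"], dtype=str)
        if mf.iloc[0, 0] == "sample_id":
            mf = mf.iloc[1:]
        base = os.path.dirname(os.path.abspath(source))
        items = [
            (sid, p if os.path.isabs(p) else os.path.join(base, p))
            for sid, p in zip(mf["sample_id"], mf["path"])
        ]
    if not items:
        raise ValidationError(f"no interval files found under {source!r}")
    return {sid: read_intervals(path, format=format) for sid, path in items}


def write_intervals(df: pd.DataFrame, path: str) -> None:
    """Write an interval frame as BED (score in column 5 when present)."""
    out = df.copy()
    if out["score"].notna().any():
        out["name"] = "."
        out = out[["chrom", "start", "end", "name", "score"]]
    else:
        out = out[["chrom", "start", "end"]]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models

def _infer_gene_format(path: str) -> str:
    low = path.lower()
    if low.endswith((".gtf", ".gtf.gz")):
        return "gtf"
    if low.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        return "gff3"
    return "tsv"


def read_gene_models(path: str, format: str | None = None) -> pd.DataFrame:
    """Read gene models, returning one TSS per gene.

    The TSS is the leftmost coordinate for ``+``-strand genes and the
    rightmost base (``end - 1``, 0-based) for ``-``-strand genes.  Duplicate
    ``gene_id`` records keep the first occurrence; the number of collisions
    is logged.
    """
    fmt = (format or _infer_gene_format(path)).lower()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
        required = {"gene_id", "chrom", "strand", "tss"}
        if not required.issubset(df.columns):
            raise ParseError(
                f"gene TSV must have columns {sorted(required)}", path=path)
    elif fmt in ("gtf", "gff3"):
        import pyranges as pr

        gr = pr.read_gtf(path) if fmt == "gtf" else pr.read_gff3(path)
        raw = gr.df
        id_col = next(
            (c for c in ("gene_id", "ID", "Name") if c in raw.columns), None)
        if id_col is None:
            raise ParseError("no gene_id/ID/Name attribute found", path=path)
        feats = raw["Feature"].unique() if "Feature" in raw.columns else []
        for feat in ("gene", "transcript", "mRNA"):
            if feat in feats:
                raw = raw[raw["Feature"] == feat]
                break
        df = pd.DataFrame({
            "gene_id": raw[id_col].astype(str),
            "chrom": raw["Chromosome"].astype(str),
            "strand": raw["Strand"].astype(str),
            "start": raw["Start"].astype(int),   # pyranges is already 0-based
            "end": raw["End"].astype(int),
        })
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    else:
        raise ValidationError(f"unknown gene-model format {fmt!r}")

    if df["strand"].isna().any() or not set(df["strand"]).issubset({"+", "-"}):
        raise ValidationError("every gene model needs strand '+' or '-'")
    if (df["tss"] < 0).any():
        raise ValidationError("negative TSS coordinate")
    n_dup = df["gene_id"].duplicated().sum()
    if n_dup:
        logger.info("read_gene_models: %d duplicate gene_id records dropped "
                    "(first kept)", n_dup)
        df = df[~df["gene_id"].duplicated()]
    return df.set_index("gene_id")[["chrom", "strand", "tss"]]


def write_gene_models(genes: pd.DataFrame, path: str) -> None:
    genes.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices and embeddings

def read_expression(path: str, format: str | None = None,
                    genes_path: str | None = None,
                    cells_path: str | None = None) -> pd.DataFrame:
    """Read a gene x cell expression matrix (dense TSV, or MTX + sidecars).

    For MTX the sidecar files default to ``genes.tsv`` / ``barcodes.tsv``
    next to the matrix.  Dimension mismatches between the matrix and the
    sidecars raise :class:`ValidationError`.
    """
    fmt = format or ("mtx" if path.lower().endswith(".mtx") else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        base = os.path.dirname(os.path.abspath(path))
        gpath = genes_path or os.path.join(base, "genes.tsv")
        cpath = cells_path or os.path.join(base, "barcodes.tsv")
        gene_ids = pd.read_csv(gpath, sep="\t", header=None)[0].astype(str)
        cell_ids = pd.read_csv(cpath, sep="\t", header=None)[0].astype(str)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                           dtype=float)
        if dense.shape != (len(gene_ids), len(cell_ids)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)")
        df = pd.DataFrame(dense, index=gene_ids.values, columns=cell_ids.values)
    else:
        raise ValidationError(f"unknown expression format {fmt!r}")
    _validate_expression(df)
    return df


def _validate_expression(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        raise ValidationError("duplicate gene identifiers")
    if df.columns.duplicated().any():
        raise ValidationError("duplicate cell identifiers")
    if (df.values < 0).any():
        raise ValidationError("expression values must be non-negative")


def write_expression(df: pd.DataFrame, path: str, format: str = "tsv") -> None:
    if format == "tsv":
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        base = os.path.dirname(os.path.abspath(path))
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(df.values))
        pd.Series(df.index).to_csv(os.path.join(base, "genes.tsv"),
                                   sep="\t", header=False, index=False)
        pd.Series(df.columns).to_csv(os.path.join(base, "barcodes.tsv"),
                                     sep="\t", header=False, index=False)
    else:
        raise ValidationError(f"unknown expression format {format!r}")


def read_embedding(path: str) -> pd.DataFrame:
    """Read a cells x 2 embedding (CSV or TSV, first column = cell id)."""
    sep = "\t" if path.lower().endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.shape[1] != 2:
        raise ValidationError(
            f"embedding must have exactly 2 coordinate columns, got {df.shape[1]}")
    df.columns = ["x", "y"]
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValidationError("duplicate cell identifiers in embedding")
    return df.astype(float)


def write_embedding(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t" if path.lower().endswith(".tsv") else ",")


def write_table(df: pd.DataFrame, path: str, params: Mapping | None = None,
                index: bool = True) -> None:
    """Write a TSV with an optional ``#``-prefixed metadata preamble."""
    with open(path, "w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)
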