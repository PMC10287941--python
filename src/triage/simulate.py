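"""Seed-deterministic synthetic data with known ground truth.

Three generators cover the pipeline's inputs end to end: a pseudo-epigenome
of per-sample H3K27me3 domain calls with planted broad-domain regulatory
genes, a toy single-cell atlas (negative-binomial counts plus a Gaussian-
blob 2D embedding with known type labels), and planted Gaussian clusters in
a PC-score space.  Every generator regenerates bit-identically from
(params, seed) and writes its truth next to its data.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as tio
from .errors import ValidationError

CHROM = "chrS"


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic data set, serialisable as JSON."""

    kind: str
    seed: int
    params: dict
    payload: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_epigenome(n_genes: int = 1000, n_samples: int = 20,
                       n_regulatory: int = 50,
                       broad_breadth_range: tuple[int, int] = (5000, 20000),
                       narrow_breadth_range: tuple[int, int] = (200, 1000),
                       regulatory_sample_fraction: float = 0.9,
                       narrow_sample_fraction: float = 0.5,
                       window_halfwidth: int = 2500,
                       seed: int = 0, out_dir: str | None = None):
    """Pseudo-epigenome with planted broad-domain regulatory genes.

    Genes sit on one synthetic chromosome, spaced so TSS windows plus the
    broadest possible domain never overlap a neighbour.  The first
    ``n_regulatory`` genes are regulatory: in ``regulatory_sample_fraction``
    of samples they carry a broad domain over their TSS, with breadth drawn
    uniformly from ``broad_breadth_range`` independently per gene and
    sample (so top-tail flags rotate across the planted set).  All other
    genes carry a narrow domain in ``narrow_sample_fraction`` of samples.

    Returns ``(intervals_by_sample, gene_models, truth)``; with ``out_dir``
    the BED files, a gene TSV and ``truth.json`` are written as well.
    """
    if n_regulatory >= n_genes:
        raise ValidationError("n_regulatory must be < n_genes")
    if broad_breadth_range[0] <= narrow_breadth_range[1]:
        raise ValidationError("broad breadth range must lie strictly above "
                              "the narrow range")
    rng = np.random.default_rng(seed)
    broad_lo, broad_hi = broad_breadth_range
    spacing = 2 * window_halfwidth + broad_hi + 1000
    tss = spacing // 2 + spacing * np.arange(n_genes)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    genes = pd.DataFrame({"chrom": CHROM, "strand": "+", "tss": tss},
                         index=pd.Index(gene_ids, name="gene_id"))

    intervals: dict[str, pd.DataFrame] = {}
    for s in range(n_samples):
        rows = []
        for i in range(n_genes):
            if i < n_regulatory:
                if rng.random() >= regulatory_sample_fraction:
                    continue
                breadth = int(rng.integers(broad_lo, broad_hi))
            else:
                if rng.random() >= narrow_sample_fraction:
                    continue
                breadth = int(rng.integers(*narrow_breadth_range))
            start = max(0, tss[i] - breadth // 2)
            rows.append((CHROM, start, start + breadth, np.nan))
        intervals[f"sample_{s:03d}"] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "score"])

    truth = SyntheticTruth(
        kind="epigenome", seed=seed,
        params={"n_genes": n_genes, "n_samples": n_samples,
                "n_regulatory": n_regulatory,
                "broad_breadth_range": list(broad_breadth_range),
                "narrow_breadth_range": list(narrow_breadth_range),
                "regulatory_sample_fraction": regulatory_sample_fraction,
                "narrow_sample_fraction": narrow_sample_fraction,
                "window_halfwidth": window_halfwidth},
        payload={"regulatory_genes": gene_ids[:n_regulatory]},
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        for sample, df in intervals.items():
            tio.write_intervals(df, os.path.join(out_dir, f"{sample}.bed"))
        tio.write_gene_models(genes, os.path.join(out_dir, "genes.tsv"))
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return intervals, genes, truth


def simulate_atlas(n_cell_types: int = 3, cells_per_type: int = 250,
                   gene_ids: list[str] | None = None,
                   marker_map: dict[str, list[str]] | None = None,
                   embedding_separation: float = 4.0, noise_sd: float = 0.4,
                   base_mean: float = 0.5, marker_boost: float = 10.0,
                   dispersion: float = 0.5, libsize_sd: float = 0.3,
                   n_genes: int = 200, seed: int = 0,
                   out_dir: str | None = None):
    """Toy single-cell atlas: NB counts + Gaussian-blob 2D embedding.

    Each cell type's marker genes (``marker_map``, type -> gene list) get a
    ``marker_boost``-fold mean shift in that type's cells.  Blob centres sit
    on a circle with pairwise distance ``embedding_separation`` and spread
    ``noise_sd``.  Without ``marker_map`` each type is assigned one marker
    from the head of ``gene_ids``.

    Returns ``(counts, embedding, labels, truth)``.
    """
    if embedding_separation <= 0:
        raise ValidationError("separation must be positive")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    types = [f"type_{t}" for t in range(n_cell_types)]
    if marker_map is None:
        marker_map = {types[t]: [gene_ids[t]] for t in range(n_cell_types)}
    flat_markers = [g for gl in marker_map.values() for g in gl]
    missing = set(flat_markers) - set(gene_ids)
    if missing:
        raise ValidationError(f"marker genes not in gene universe: "
                              f"{sorted(missing)[:5]}")

    n_cells = n_cell_types * cells_per_type
    labels = pd.Series(np.repeat(types, cells_per_type),
                       index=[f"cell_{i:04d}" for i in range(n_cells)],
                       name="cell_type")

    gidx = {g: i for i, g in enumerate(gene_ids)}
    base = base_mean * rng.lognormal(0.0, 1.0, size=len(gene_ids))
    means = np.tile(base[:, None], (1, n_cells))
    for t, genes_t in marker_map.items():
        cols = np.flatnonzero(labels.values == t)
        for g in genes_t:
            means[gidx[g], cols] *= marker_boost
    libsize = rng.lognormal(0.0, libsize_sd, size=n_cells)
    means = means * libsize[None, :]
    # NB with var = m + m^2 * dispersion
    r = 1.0 / dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)
    counts = pd.DataFrame(counts.astype(float), index=gene_ids,
                          columns=labels.index)

    # embedding: blob centres on a circle with the requested pairwise gap
    if n_cell_types == 1:
        centres = np.zeros((1, 2))
    else:
        radius = embedding_separation / (2 * np.sin(np.pi / n_cell_types))
        ang = 2 * np.pi * np.arange(n_cell_types) / n_cell_types
        centres = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    coords = np.vstack([
        centres[t] + rng.normal(0, noise_sd, size=(cells_per_type, 2))
        for t in range(n_cell_types)])
    embedding = pd.DataFrame(coords, index=labels.index, columns=["x", "y"])

    truth = SyntheticTruth(
        kind="atlas", seed=seed,
        params={"n_cell_types": n_cell_types, "cells_per_type": cells_per_type,
                "embedding_separation": embedding_separation,
                "noise_sd": noise_sd, "base_mean": base_mean,
                "marker_boost": marker_boost, "dispersion": dispersion,
                "libsize_sd": libsize_sd},
        payload={"marker_map": {k: list(v) for k, v in marker_map.items()},
                 "labels": labels.to_dict()},
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        tio.write_expression(counts, os.path.join(out_dir, "counts.tsv"))
        tio.write_embedding(embedding, os.path.join(out_dir, "embedding.csv"))
        labels.to_csv(os.path.join(out_dir, "labels.tsv"), sep="\t")
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return counts, embedding, labels, truth


def simulate_pc_clusters(n_genes: int = 100, n_clusters: int = 3,
                         dim: int = 10, separation: float = 8.0,
                         seed: int = 0, out_dir: str | None = None):
    """Planted spherical Gaussian clusters in a PC-score space.

    Cluster centres are placed at ``separation / sqrt(2)`` along distinct
    coordinate axes, giving exact pairwise centre distance ``separation``
    in units of the within-cluster standard deviation (1).

    Returns ``(features, labels, truth)``.
    """
    if dim < 1:
        raise ValidationError("dim must be >= 1")
    if n_clusters > n_genes:
        raise ValidationError("n_clusters must be <= n_genes")
    if n_clusters > dim:
        raise ValidationError("n_clusters must be <= dim for axis placement")
    rng = np.random.default_rng(seed)
    centres = np.zeros((n_clusters, dim))
    if n_clusters > 1:
        for k in range(n_clusters):
            centres[k, k] = separation / np.sqrt(2.0)
    sizes = np.full(n_clusters, n_genes // n_clusters)
    sizes[: n_genes % n_clusters] += 1
    feats, labs = [], []
    for k in range(n_clusters):
        feats.append(centres[k] + rng.normal(0, 1, size=(sizes[k], dim)))
        labs.extend([k] * sizes[k])
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    features = pd.DataFrame(np.vstack(feats), index=gene_ids,
                            columns=[f"PC{j + 1}" for j in range(dim)])
    labels = pd.Series(labs, index=gene_ids, name="cluster")
    truth = SyntheticTruth(
        kind="pc_clusters", seed=seed,
        params={"n_genes": n_genes, "n_clusters": n_clusters, "dim": dim,
                "separation": separation},
        payload={"labels": labels.to_dict()},
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        features.to_csv(os.path.join(out_dir, "features.tsv"), sep="\t")
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return features, labels, truth


def simulate_program_breadth(n_genes: int = 1000, n_samples: int = 45,
                             n_programs: int = 3, genes_per_program: int = 60,
                             program_breadth: float = 15000.0,
                             breadth_sd: float = 1500.0,
                             background_breadth: float = 500.0,
                             seed: int = 0):
    """Breadth matrix with planted orthogonal deposition programs.

    The samples are split into ``n_programs`` equal groups; each program's
    genes carry broad domains (mean ``program_breadth``) only in their
    group's samples, on top of low background breadth everywhere.

    Returns ``(breadth, gene_programs)`` with ``gene_programs`` mapping each
    program gene to its program index.
    """
    if n_programs * genes_per_program > n_genes:
        raise ValidationError("too many program genes for the universe")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"sample_{j:03d}" for j in range(n_samples)]
    breadth = rng.exponential(background_breadth, size=(n_genes, n_samples))
    group = np.arange(n_samples) % n_programs
    programs = {}
    for p in range(n_programs):
        rows = range(p * genes_per_program, (p + 1) * genes_per_program)
        cols = np.flatnonzero(group == p)
        for i in rows:
            breadth[i, cols] += np.abs(
                rng.normal(program_breadth, breadth_sd, size=cols.size))
            programs[gene_ids[i]] = p
    return (pd.DataFrame(breadth, index=gene_ids, columns=samples),
            pd.Series(programs, name="program"))
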