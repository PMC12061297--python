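"""scRNA-seq QC, normalization/PCA, and the radius of genomic space.

Intercellular transcriptional heterogeneity is measured as the root-mean-
square distance of cells from their centroid in a 3D expression embedding,

    Rc = sqrt( (1/N) * sum_i || r_i - r_mean ||^2 ),

computed per condition after standard single-cell preprocessing: QC
filtering (library size 20k-100k reads, < 15% mitochondrial expression,
>= 200 detected features, genes seen in >= 3 cells), log-normalization with
a 1e4 scale factor, highly-variable-gene selection, per-gene scaling, and
PCA (dimensions 1-20).  The 3D embedding step (t-SNE in typical use) is a
pluggable contract; a deterministic first-three-PCs fallback ships so
results never depend on a stochastic embedder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CellMatrix:
    """Cell x gene count matrix with derived per-cell QC metrics."""

    counts: pd.DataFrame  # cells x genes, nonnegative integers
    mito_prefix: str = "MT"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate cell ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_features(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    @property
    def mito_fraction(self) -> pd.Series:
        mito_cols = [g for g in self.counts.columns if g.startswith(self.mito_prefix)]
        totals = self.total_reads
        if not mito_cols:
            return pd.Series(0.0, index=self.counts.index)
        frac = self.counts[mito_cols].sum(axis=1) / totals.replace(0, np.nan)
        return frac.fillna(0.0)

    @property
    def genes_per_umi(self) -> pd.Series:
        totals = self.total_reads
        return self.n_features / totals.replace(0, np.nan)


@dataclass
class Embedding:
    """Per-cell 3D coordinates with condition labels."""

    coords: pd.DataFrame  # index cell id; columns x, y, z
    conditions: pd.Series  # cell id -> condition label

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords.to_numpy())):
            raise ValueError("non-finite embedding coordinates")
        self.conditions = self.conditions.reindex(self.coords.index)
        if self.conditions.isna().any():
            raise ValueError("cells without a condition label")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def qc_filter(
    cells: CellMatrix,
    min_features: int = 200,
    min_cells_per_gene: int = 3,
    min_reads: int = 20_000,
    max_reads: int = 100_000,
    max_mito: float = 0.15,
) -> tuple[CellMatrix, dict]:
    """Standard scRNA QC with Seurat-style boundary semantics.

    Gene filter first (genes detected in >= ``min_cells_per_gene`` cells),
    then cells are removed when reads < ``min_reads``, reads >
    ``max_reads``, mito fraction >= ``max_mito`` (15% *or more* removed),
    or detected features < ``min_features``.  The report attributes each
    removed cell to every rule it violates.
    """
    counts = cells.counts
    gene_keep = (counts > 0).sum(axis=0) >= min_cells_per_gene
    counts = counts.loc[:, gene_keep]
    filtered = CellMatrix(counts, cells.mito_prefix)

    reads = filtered.total_reads
    feats = filtered.n_features
    mito = filtered.mito_fraction
    low_reads = reads < min_reads
    high_reads = reads > max_reads
    high_mito = mito >= max_mito
    low_features = feats < min_features
    fail = low_reads | high_reads | high_mito | low_features
    survivors = counts.index[~fail]
    report = {
        "input_cells": int(len(counts)),
        "genes_removed": int((~gene_keep).sum()),
        "removed_low_reads": int(low_reads.sum()),
        "removed_high_reads": int(high_reads.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_low_features": int(low_features.sum()),
        "removed_cells": int(fail.sum()),
        "surviving_cells": int(len(survivors)),
        "thresholds": {
            "min_features": min_features,
            "min_cells_per_gene": min_cells_per_gene,
            "min_reads": min_reads,
            "max_reads": max_reads,
            "max_mito": max_mito,
        },
    }
    if len(survivors) == 0:
        raise ValueError(f"no cells survive QC: {report}")
    return CellMatrix(counts.loc[survivors], cells.mito_prefix), report


def lognormalize(counts: pd.DataFrame, scale_factor: float = 1e4) -> pd.DataFrame:
    """Per-cell depth normalization: x -> ln(1 + count / total * scale_factor)."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter first")
    return np.log1p(counts.div(totals, axis=0) * scale_factor)


def lognorm_hvg_scale(
    cells: CellMatrix,
    scale_factor: float = 1e4,
    n_hvg: int = 2000,
    clip: float = 10.0,
) -> pd.DataFrame:
    """Log-normalize, pick highly variable genes, and z-scale them.

    Normalization: x -> ln(1 + count / cell_total * scale_factor).  HVGs are
    ranked by variance standardized against a rank-based running-median
    mean-variance trend (a loess-free variance-stabilizing selection).  The
    selected gene columns are centered, scaled to unit variance and clipped
    at +/- ``clip``; constant genes are excluded from selection.
    """
    norm = lognormalize(cells.counts, scale_factor)

    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    # tolerance absorbs float dust on genes that are constant across cells
    nonconst = var > 1e-12 * max(1.0, float(var.max()))
    if not nonconst.any():
        raise ValueError("all genes constant; HVG selection impossible")
    mean_nc, var_nc = mean[nonconst], var[nonconst]
    order = mean_nc.sort_values(kind="stable").index
    trend = var_nc.loc[order].rolling(window=51, center=True, min_periods=1).median()
    standardized = (var_nc.loc[order] / trend).sort_values(
        ascending=False, kind="stable"
    )
    hvgs = standardized.index[: min(n_hvg, len(standardized))]

    sub = norm[hvgs]
    scaled = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    return scaled.clip(-clip, clip)


def pca_embed(scaled: pd.DataFrame, n_components: int = 20) -> pd.DataFrame:
    """SVD-based PCA with a deterministic sign convention.

    Each component is flipped so its largest-|loading| entry is positive;
    explained variance is non-increasing by construction.
    """
    x = scaled.to_numpy(dtype=float)
    n_cells, n_genes = x.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)="
            f"{min(n_cells, n_genes)}"
        )
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if rank < n_components:
        raise ValueError(f"data rank {rank} below requested {n_components} components")
    # sign convention: largest-|loading| coefficient of each PC is positive
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    pcs = u[:, :n_components] * s[:n_components]
    return pd.DataFrame(
        pcs,
        index=scaled.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


def pca_fallback_embedding(pcs: pd.DataFrame) -> np.ndarray:
    """Deterministic 3D embedding contract: the first three PCs."""
    if pcs.shape[1] < 3:
        raise ValueError("need at least 3 components for a 3D embedding")
    return pcs.to_numpy()[:, :3]


def embed_cells(
    cells: CellMatrix,
    conditions: pd.Series,
    embedder=None,
    n_components: int = 20,
    n_hvg: int = 2000,
) -> Embedding:
    """Preprocess and embed a QC'd matrix into 3D.

    ``embedder`` is any callable mapping the (cells x n_components) PC
    matrix to (cells x 3) coordinates — a 3D t-SNE in typical use.  The
    default is the deterministic first-three-PCs fallback.
    """
    scaled = lognorm_hvg_scale(cells, n_hvg=n_hvg)
    n_components = min(n_components, min(scaled.shape) - 1)
    pcs = pca_embed(scaled, n_components=n_components)
    coords = (embedder or pca_fallback_embedding)(pcs)
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(pcs), 3):
        raise ValueError("embedder must return (n_cells, 3) coordinates")
    return Embedding(
        pd.DataFrame(coords, index=pcs.index, columns=["x", "y", "z"]),
        conditions,
    )


def _rc(points: np.ndarray, weights: np.ndarray | None = None) -> float:
    if weights is None:
        center = points.mean(axis=0)
        msd = float(np.mean(np.sum((points - center) ** 2, axis=1)))
    else:
        w = weights / weights.sum()
        center = (points * w[:, None]).sum(axis=0)
        msd = float((w * np.sum((points - center) ** 2, axis=1)).sum())
    return float(np.sqrt(msd))


def radius_of_genomic_space(
    emb: Embedding,
    equalize: str = "subsample",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition RMS radius of the 3D embedding cloud.

    ``equalize`` controls how unequal condition sizes are handled before
    comparing radii:

    - ``"none"``: Rc on all cells of each condition;
    - ``"subsample"`` (default): each condition is down-sampled without
      replacement, with ``seed``, to the smallest condition's cell count;
    - ``"weights"``: Rc from the uniformly weighted mean/sum form (each
      cell weighted 1/N of its condition), the analytic counterpart of
      subsampling.

    Returns a table (condition, n_cells, n_used, rc, equalize, seed).
    Rc is invariant to rigid rotations and translations of the embedding.
    """
    if equalize not in ("none", "subsample", "weights"):
        raise ValueError(f"unknown equalize mode {equalize!r}")
    rng = np.random.default_rng(seed)
    groups = {
        cond: emb.coords.loc[idx].to_numpy()
        for cond, idx in emb.conditions.groupby(emb.conditions).groups.items()
    }
    for cond, pts in groups.items():
        if len(pts) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 cells")
    n_min = min(len(p) for p in groups.values())
    rows = []
    for cond, pts in groups.items():
        if equalize == "subsample":
            take = rng.choice(len(pts), size=n_min, replace=False)
            used = pts[np.sort(take)]
            rc = _rc(used)
            n_used = n_min
        elif equalize == "weights":
            rc = _rc(pts, weights=np.full(len(pts), 1.0 / len(pts)))
            n_used = len(pts)
        else:
            rc = _rc(pts)
            n_used = len(pts)
        rows.append(
            {
                "condition": cond,
                "n_cells": len(pts),
                "n_used": n_used,
                "rc": rc,
                "equalize": equalize,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
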