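"""Peak-level chromatin-mark analytics.

Operations on histone-mark peak sets (H3K4me3, H3K27me3, H3K27ac, ...):
differential-peak gating, per-chromosome mark density with cross-mark
regression, poised (bivalent) promoter calling in a TSS +/- 2 kb window,
genomic feature annotation of peaks, and promoter log2-fold-change signal
matrices with K-means clustering.

Coordinate convention is BED-style throughout: 0-based, half-open
``[start, end)``.  Promoter windows are half-open ``[TSS-w, TSS+w)`` and a
peak is associated with a gene iff peak and window overlap by at least 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.cluster import KMeans

PEAK_COLUMNS = ("chrom", "start", "end")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """A set of genomic intervals for one histone mark.

    ``intervals`` holds columns chrom/start/end plus optional ``p_value``
    and ``direction`` columns (direction: 'up'/'down' in CSC vs non-CSC).
    """

    mark: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals)
        missing = [c for c in PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"PeakSet missing columns: {missing}")
        df = df.reset_index(drop=True)
        bad = df["start"] >= df["end"]
        if bad.any():
            rows = df.index[bad].tolist()
            raise ValueError(f"intervals with start >= end at rows {rows}")
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_against_sizes(self, chrom_sizes: dict[str, int]) -> None:
        for chrom, sub in self.intervals.groupby("chrom"):
            if chrom not in chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} not in chrom_sizes")
            over = sub[sub["end"] > chrom_sizes[chrom]]
            if len(over):
                row = over.iloc[0]
                raise ValueError(
                    f"peak {row['chrom']}:{row['start']}-{row['end']} exceeds "
                    f"chromosome length {chrom_sizes[chrom]}"
                )


@dataclass
class GeneAnnotation:
    """Minimal gene annotation: canonical TSS per gene.

    ``genes`` columns: gene_id, chrom, strand, tss.  The promoter window of
    a gene is ``[tss - window, tss + window)`` (window defaults to 2 kb
    downstream consumers).
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.genes).reset_index(drop=True)
        required = ["gene_id", "chrom", "strand", "tss"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"GeneAnnotation missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if (df["tss"] < 0).any():
            raise ValueError("negative TSS coordinate")
        self.genes = df

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ChromDensityTable:
    """Per-chromosome merged-bp density of one mark.

    density = merged peak bp / chromosome length, a dimensionless fraction
    in [0, 1] (guaranteed by interval merging before summation).
    """

    mark: str
    table: pd.DataFrame  # chrom, merged_bp, chrom_length, density

    def densities(self, chroms: list[str] | None = None) -> pd.Series:
        s = self.table.set_index("chrom")["density"]
        return s.loc[chroms] if chroms is not None else s


@dataclass
class PoisedCallResult:
    """Poised (H3K4me3 + H3K27me3 bivalent) gene calls per cell type."""

    poised: dict[str, frozenset[str]]
    shared: frozenset[str] = field(init=False)
    counts: dict[str, int] = field(init=False)
    fold_ratio: float | None = field(init=False)

    def __post_init__(self) -> None:
        sets = list(self.poised.values())
        self.shared = frozenset.intersection(*sets) if sets else frozenset()
        self.counts = {k: len(v) for k, v in self.poised.items()}
        self.fold_ratio = None
        if len(sets) == 2:
            a, b = sets
            if len(b) > 0:
                self.fold_ratio = len(a) / len(b)


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------

def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping half-open intervals; returns sorted, disjoint."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:  # overlapping or bookended -> coalesce
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def gate_differential(peaks: PeakSet, p_max: float) -> tuple[PeakSet, dict]:
    """Retain differential peaks with strict ``p_value < p_max``.

    Returns the gated PeakSet and a count report
    ``{"input": n, "retained": k, "removed": n-k, "p_max": p_max}``.
    """
    if "p_value" not in peaks.intervals.columns:
        raise ValueError("gate_differential requires a p_value column")
    df = peaks.intervals
    if df["p_value"].isna().any():
        raise ValueError("missing p-values in peak set")
    keep = df["p_value"] < p_max
    gated = PeakSet(peaks.mark, df[keep].reset_index(drop=True))
    report = {
        "input": int(len(df)),
        "retained": int(keep.sum()),
        "removed": int((~keep).sum()),
        "p_max": float(p_max),
    }
    return gated, report


def per_chromosome_density(
    peaks: PeakSet,
    chrom_sizes: dict[str, int],
    exclude: set[str] = frozenset({"chrX"}),
) -> ChromDensityTable:
    """Merged-bp per chromosome normalized to chromosome length.

    Overlapping intervals are merged before summation so density <= 1.
    Chromosome X is excluded by default (distinct heterochromatin mechanics).
    Chromosomes in ``chrom_sizes`` with no peaks get density 0.
    """
    peaks.validate_against_sizes(chrom_sizes)
    rows = []
    by_chrom = dict(tuple(peaks.intervals.groupby("chrom")))
    for chrom, length in chrom_sizes.items():
        if chrom in exclude:
            continue
        sub = by_chrom.get(chrom)
        if sub is None:
            merged_bp = 0
        else:
            s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            merged_bp = int((e - s).sum())
        rows.append(
            {
                "chrom": chrom,
                "mark": peaks.mark,
                "merged_bp": merged_bp,
                "chrom_length": int(length),
                "density": merged_bp / length,
            }
        )
    return ChromDensityTable(peaks.mark, pd.DataFrame(rows))


def density_regression(table_a: ChromDensityTable, table_b: ChromDensityTable) -> dict:
    """OLS of B-density on A-density across shared chromosomes.

    Returns slope, intercept, r2 (squared Pearson correlation), n_chrom.
    """
    shared = sorted(
        set(table_a.table["chrom"]) & set(table_b.table["chrom"])
    )
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared chromosomes, got {len(shared)}")
    x = table_a.densities(shared).to_numpy(dtype=float)
    y = table_b.densities(shared).to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor densities")
    if np.ptp(y) == 0:  # flat response: slope and R^2 are exactly 0
        return {"slope": 0.0, "intercept": float(y[0]), "r2": 0.0,
                "n_chrom": len(shared)}
    fit = _stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "n_chrom": len(shared),
    }


def assign_peaks_to_tss(
    peaks: PeakSet, annotation: GeneAnnotation, window: int = 2000
) -> dict[str, list[int]]:
    """Associate peaks with genes whose promoter window they overlap.

    A peak is assigned to gene g iff ``[tss - window, tss + window)``
    overlaps the peak by >= 1 bp; a peak may hit several genes and strand
    does not alter the window.  Returns gene_id -> list of peak row indices.
    """
    out: dict[str, list[int]] = {}
    by_chrom: dict[str, pd.DataFrame] = dict(tuple(peaks.intervals.groupby("chrom")))
    for _, gene in annotation.genes.iterrows():
        sub = by_chrom.get(gene["chrom"])
        hits: list[int] = []
        if sub is not None:
            w_lo = gene["tss"] - window
            w_hi = gene["tss"] + window
            ov = (sub["start"] < w_hi) & (sub["end"] > w_lo)
            hits = sub.index[ov].tolist()
        out[gene["gene_id"]] = hits
    return out


def call_poised(
    assignments: dict[str, dict[str, dict[str, list[int]]]]
) -> PoisedCallResult:
    """Call poised genes per cell type from mark->gene assignments.

    ``assignments`` maps cell type -> {"H3K4me3": assign, "H3K27me3": assign}
    where each assign is the output of :func:`assign_peaks_to_tss`.  A gene
    is poised when it has at least one peak of each mark in its window.
    """
    poised: dict[str, frozenset[str]] = {}
    gene_universe: set[frozenset[str]] = set()
    for cell_type, marks in assignments.items():
        if "H3K4me3" not in marks or "H3K27me3" not in marks:
            raise ValueError("call_poised needs H3K4me3 and H3K27me3 assignments")
        k4, k27 = marks["H3K4me3"], marks["H3K27me3"]
        if set(k4) != set(k27):
            raise ValueError("mark assignments cover different annotations")
        gene_universe.add(frozenset(k4))
        poised[cell_type] = frozenset(
            g for g in k4 if k4[g] and k27[g]
        )
    if len(gene_universe) > 1:
        raise ValueError("cell types annotated over different gene sets")
    return PoisedCallResult(poised)


FEATURE_PRIORITY = ("promoter", "exon", "intron", "intergenic")


def annotate_peak_features(
    peaks: PeakSet,
    annotation: GeneAnnotation,
    gene_models: pd.DataFrame,
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Classify each peak by its midpoint with priority promoter > exon > intron > intergenic.

    ``gene_models`` columns: gene_id, chrom, start, end, feature ('exon') —
    exon intervals; the gene span is the hull of its exons, so a midpoint
    inside the span but in no exon is intronic.  Returns per-category counts
    and fractions for the peak set's mark.
    """
    exons = gene_models[gene_models["feature"] == "exon"]
    spans = (
        exons.groupby(["gene_id", "chrom"])
        .agg(start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    categories = []
    for _, pk in peaks.intervals.iterrows():
        mid = (pk["start"] + pk["end"]) // 2
        chrom = pk["chrom"]
        genes_here = annotation.genes[annotation.genes["chrom"] == chrom]
        in_promoter = (
            (genes_here["tss"] - promoter_window <= mid)
            & (mid < genes_here["tss"] + promoter_window)
        ).any()
        if in_promoter:
            categories.append("promoter")
            continue
        ex_here = exons[exons["chrom"] == chrom]
        if ((ex_here["start"] <= mid) & (mid < ex_here["end"])).any():
            categories.append("exon")
            continue
        sp_here = spans[spans["chrom"] == chrom]
        if ((sp_here["start"] <= mid) & (mid < sp_here["end"])).any():
            categories.append("intron")
        else:
            categories.append("intergenic")
    counts = pd.Series(categories, dtype="object").value_counts()
    out = pd.DataFrame(
        {
            "category": FEATURE_PRIORITY,
            "count": [int(counts.get(c, 0)) for c in FEATURE_PRIORITY],
        }
    )
    total = out["count"].sum()
    out["fraction"] = out["count"] / total if total else 0.0
    out.insert(0, "mark", peaks.mark)
    return out


def promoter_signal_matrix(
    coverage_a: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    coverage_b: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    annotation: GeneAnnotation,
    window: int = 2000,
    bin_size: int = 50,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Per-gene, per-bin promoter log2 fold-change matrix, deeptools-style.

    Coverage tracks are per-chromosome ``(starts, ends, values)`` bedGraph
    triples.  For each gene the window ``[tss-window, tss+window)`` is cut
    into ``2*window/bin_size`` bins, mean coverage is computed per bin for
    each track, and the matrix entry is ``log2((A+pc)/(B+pc))``.  Rows of
    minus-strand genes are reversed so bins always run 5'->3'.

    Returns (matrix, n_skipped) where skipped genes had promoters off the
    covered contigs or out of range.
    """
    if (2 * window) % bin_size != 0:
        raise ValueError("bin size must evenly divide the window")
    n_bins = (2 * window) // bin_size
    rows, index = [], []
    skipped = 0
    for _, gene in annotation.genes.iterrows():
        chrom = gene["chrom"]
        lo = gene["tss"] - window
        if chrom not in coverage_a or chrom not in coverage_b or lo < 0:
            skipped += 1
            continue
        prof_a = _binned_means(coverage_a[chrom], lo, n_bins, bin_size)
        prof_b = _binned_means(coverage_b[chrom], lo, n_bins, bin_size)
        lfc = np.log2((prof_a + pseudocount) / (prof_b + pseudocount))
        if gene["strand"] == "-":
            lfc = lfc[::-1]
        rows.append(lfc)
        index.append(gene["gene_id"])
    matrix = pd.DataFrame(
        rows, index=index, columns=[f"bin_{i}" for i in range(n_bins)]
    )
    return matrix, skipped


def _binned_means(
    track: tuple[np.ndarray, np.ndarray, np.ndarray],
    window_start: int,
    n_bins: int,
    bin_size: int,
) -> np.ndarray:
    starts, ends, values = (np.asarray(a) for a in track)
    out = np.zeros(n_bins)
    for i in range(n_bins):
        lo = window_start + i * bin_size
        hi = lo + bin_size
        ov = np.minimum(ends, hi) - np.maximum(starts, lo)
        ov = np.clip(ov, 0, None)
        out[i] = float((ov * values).sum()) / bin_size  # uncovered bp counts as 0
    return out


def cluster_promoters(
    matrix: pd.DataFrame, k: int = 6, seed: int = 0, n_restarts: int = 10
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means (Lloyd, k-means++ init, best of ``n_restarts``) on the LFC matrix.

    Returns per-gene labels and per-cluster metaplot (per-bin mean).
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of rows {len(matrix)}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(matrix.to_numpy())
    labels = pd.Series(km.labels_, index=matrix.index, name="cluster")
    metaplot = matrix.groupby(labels).mean()
    metaplot.index.name = "cluster"
    return labels, metaplot
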