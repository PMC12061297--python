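"""Readers and writers for the standard formats the pipeline touches.

BED (peaks), bedGraph (coverage), TSV (counts, chromosome sizes, gene
annotation), MTX triplets (single-cell counts), and NPZ / multi-page TIFF
spectral cubes.  All writes go through a temp-file + rename so outputs are
never left half-written.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as _spio
import scipy.sparse as _sparse

from .heterogeneity import CellMatrix
from .marks import GeneAnnotation, PeakSet
from .plasticity import ExpressionTable
from .pws import SpectralCube


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, mark: str | None = None) -> PeakSet:
    """Read a BED-like peak file (>= 3 tab-separated columns).

    Column 4, if numeric, is taken as p_value; column 5 as direction.
    Malformed lines (start >= end, non-integer coordinates, too few
    columns) raise with their line numbers.
    """
    path = Path(path)
    rows, errors = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                errors.append(f"line {lineno}: fewer than 3 columns")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if start >= end:
                errors.append(f"line {lineno}: start >= end ({start} >= {end})")
                continue
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) >= 4:
                try:
                    row["p_value"] = float(parts[3])
                except ValueError:
                    pass
            if len(parts) >= 5:
                row["direction"] = parts[4]
            rows.append(row)
    if errors:
        raise ValueError(f"malformed BED {path}: " + "; ".join(errors))
    return PeakSet(mark or path.stem, pd.DataFrame(rows, columns=None if rows else ["chrom", "start", "end"]))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    def _write(tmp: Path) -> None:
        cols = ["chrom", "start", "end"]
        for extra in ("p_value", "direction"):
            if extra in peaks.intervals.columns:
                cols.append(extra)
        peaks.intervals[cols].to_csv(tmp, sep="\t", header=False, index=False)

    _atomic_write(Path(path), _write)


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """bedGraph coverage as per-chromosome (starts, ends, values) arrays."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    out = {}
    for chrom, sub in df.groupby("chrom"):
        out[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["value"].to_numpy(float),
        )
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    _atomic_write(
        Path(path),
        lambda tmp: pd.DataFrame(sizes.items()).to_csv(
            tmp, sep="\t", header=False, index=False
        ),
    )


def read_annotation(path: str | Path) -> GeneAnnotation:
    """4-column annotation TSV with header: gene_id, chrom, strand, tss."""
    return GeneAnnotation(pd.read_csv(path, sep="\t"))


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    _atomic_write(
        Path(path), lambda tmp: annotation.genes.to_csv(tmp, sep="\t", index=False)
    )


def read_counts_tsv(
    path: str | Path, samples_path: str | Path | None = None
) -> ExpressionTable:
    """Bulk counts TSV: gene_id, length, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    df = df.set_index("gene_id")
    lengths = df.pop("length") if "length" in df.columns else None
    samples = None
    if samples_path is not None:
        samples = pd.read_csv(samples_path, sep="\t").set_index("sample")
    return ExpressionTable(values=df, lengths=lengths, samples=samples)


def write_counts_tsv(table: ExpressionTable, path: str | Path) -> None:
    def _write(tmp: Path) -> None:
        out = table.values.copy()
        if table.lengths is not None:
            out.insert(0, "length", table.lengths)
        out.to_csv(tmp, sep="\t", index_label="gene_id")

    _atomic_write(Path(path), _write)


# ---------------------------------------------------------------------------
# single-cell MTX triplet
# ---------------------------------------------------------------------------

def read_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    mito_prefix: str = "MT",
) -> CellMatrix:
    """MTX triplet (genes x cells matrix, gene list, cell list) -> CellMatrix."""
    matrix = _spio.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
    dense = np.asarray(matrix.todense() if _sparse.issparse(matrix) else matrix)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match {len(genes)} genes x "
            f"{len(cells)} cells"
        )
    if len(set(genes)) != len(genes):
        dups = pd.Series(genes)[pd.Series(genes).duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    counts = pd.DataFrame(dense.T, index=cells, columns=genes)
    return CellMatrix(counts, mito_prefix=mito_prefix)


def write_mtx(
    cells: CellMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    sparse = _sparse.coo_matrix(cells.counts.to_numpy().T)

    def _write_matrix(tmp: Path) -> None:
        with open(tmp, "wb") as fh:  # handle keeps mmwrite off suffix games
            _spio.mmwrite(fh, sparse)

    _atomic_write(Path(mtx_path), _write_matrix)
    _atomic_write(
        Path(genes_path),
        lambda tmp: pd.Series(cells.counts.columns).to_csv(
            tmp, sep="\t", header=False, index=False
        ),
    )
    _atomic_write(
        Path(cells_path),
        lambda tmp: pd.Series(cells.counts.index).to_csv(
            tmp, sep="\t", header=False, index=False
        ),
    )


# ---------------------------------------------------------------------------
# spectral cubes
# ---------------------------------------------------------------------------

def read_cube_npz(path: str | Path) -> SpectralCube:
    with np.load(path) as data:
        return SpectralCube(data["intensities"], data["wavelengths"], data["reference"])


def write_cube_npz(cube: SpectralCube, path: str | Path) -> None:
    def _write(tmp: Path) -> None:
        with open(tmp, "wb") as fh:  # file handle avoids numpy suffix games
            np.savez_compressed(
                fh,
                intensities=cube.intensities,
                wavelengths=cube.wavelengths,
                reference=cube.reference,
            )

    _atomic_write(Path(path), _write)


def read_cube_tiff(
    tiff_path: str | Path, wavelengths_path: str | Path, reference_path: str | Path
) -> SpectralCube:
    """Multi-page TIFF stack + wavelengths TSV + reference TIFF stack."""
    import tifffile

    intensities = tifffile.imread(str(tiff_path))
    reference = tifffile.imread(str(reference_path))
    wl = pd.read_csv(wavelengths_path, sep="\t", header=None)[0].to_numpy(float)
    return SpectralCube(intensities, wl, reference)


def write_cube_tiff(
    cube: SpectralCube,
    tiff_path: str | Path,
    wavelengths_path: str | Path,
    reference_path: str | Path,
) -> None:
    import tifffile

    _atomic_write(
        Path(tiff_path),
        lambda tmp: tifffile.imwrite(
            str(tmp), cube.intensities.astype(np.float32), photometric="minisblack"
        ),
    )
    _atomic_write(
        Path(reference_path),
        lambda tmp: tifffile.imwrite(
            str(tmp), cube.reference.astype(np.float32), photometric="minisblack"
        ),
    )
    _atomic_write(
        Path(wavelengths_path),
        lambda tmp: pd.Series(cube.wavelengths).to_csv(
            tmp, sep="\t", header=False, index=False
        ),
    )
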