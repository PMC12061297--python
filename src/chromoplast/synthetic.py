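"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here so that all
downstream stages are testable without any external download: PWS spectral
cubes whose per-pixel spectral variance encodes a known chromatin-packing
map, bulk expression tables with a planted low-baseline fold-change
structure (bimodal for the CSC-like cell type, unimodal positive for the
non-CSC-like one), 3D embeddings of known spread, histone-mark peak sets
with a planted cross-mark per-chromosome density correlation, gene
annotations with planted bivalent (poised) promoters, and single-cell
count matrices with planted QC failures.

Each generator returns its ground truth alongside the data; recovery tests
feed only the data into the analysis modules and compare against the
truth.  All randomness flows through ``numpy.random.default_rng`` seeded
from the config, so identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .heterogeneity import CellMatrix, Embedding
from .marks import GeneAnnotation, PeakSet, merge_intervals
from .plasticity import ExpressionTable
from .pws import DEFAULT_WAVELENGTHS, CalibrationModel, SpectralCube


def _toy_chrom_sizes() -> dict[str, int]:
    """22 autosomes with decreasing sizes plus chrX (excluded downstream)."""
    sizes = {f"chr{i}": int(2_000_000 - (i - 1) * 60_000) for i in range(1, 23)}
    sizes["chrX"] = 1_500_000
    return sizes


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the simulated regime the analyses are validated
    against: 30 nuclei per group with nuclear packing scaling centered at
    2.34 (CSC-like) vs 2.05 (non-CSC-like, sd 0.1), spectra on the
    515-685 nm / 2 nm grid, 5% spectral noise, a 0.82 cross-mark
    per-chromosome density correlation, and a 100-cell single-cell matrix.
    """

    seed: int = 0
    # PWS
    n_nuclei_per_group: int = 30
    true_dn_means: dict[str, float] = field(
        default_factory=lambda: {"ALDH+": 2.34, "ALDH-": 2.05}
    )
    true_dn_sd: float = 0.1
    cube_shape: tuple[int, int, int] = (86, 24, 24)
    wavelengths: np.ndarray = field(
        default_factory=lambda: DEFAULT_WAVELENGTHS.copy()
    )
    calib_params: dict = field(default_factory=lambda: {"b": 0.05})
    noise_frac: float = 0.05  # spectral noise sd as a fraction of signal sigma
    # bulk expression
    n_genes: int = 2000
    n_replicates: int = 2
    dispersion: float = 0.1
    lfc_mu: float = 2.0
    lfc_mixture_weights: tuple[float, float] = (0.5, 0.5)
    lfc_component_sd: float = 0.25
    lfc_background_sd: float = 0.2
    n_ercc: int = 10
    # single cell
    n_cells: int = 100
    # genome / peaks
    chrom_sizes: dict[str, int] = field(default_factory=_toy_chrom_sizes)
    planted_rho: float = 0.82
    planted_poised: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.wavelengths = wl
        for name in ("n_nuclei_per_group", "n_genes", "n_cells", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 <= self.planted_rho <= 1.0:
            raise ValueError("planted_rho must lie in [-1, 1]")
        if not 0 < sum(self.lfc_mixture_weights) <= 1 + 1e-12:
            raise ValueError("mixture weights must sum to 1")
        self.planted_poised = frozenset(self.planted_poised)

    def calibration(self) -> CalibrationModel:
        return CalibrationModel("linear", dict(self.calib_params))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# PWS cubes
# ---------------------------------------------------------------------------

def gen_pws_cube(
    d_map: np.ndarray,
    mask: np.ndarray,
    calib: CalibrationModel,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    reference_level: float = 1000.0,
) -> SpectralCube:
    """Spectral cube whose normalized per-pixel spectral sd encodes ``d_map``.

    Each pixel's reference-normalized spectrum is 1 plus a smooth in-band
    interference-like waveform, exactly standardized to zero mean and unit
    sample standard deviation, scaled by ``calib.forward(D)``; with
    ``noise_sd`` = 0 the normalized spectral sd therefore equals
    ``calib.forward(D)`` to floating-point precision.  ``noise_sd`` adds
    white Gaussian measurement noise on the normalized intensity, the
    high-frequency component the Butterworth low-pass is there to remove.
    """
    d_map = np.asarray(d_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if d_map.shape != mask.shape:
        raise ValueError("d_map / mask shape mismatch")
    calib.check_domain(d_map)
    rng = _rng(seed)
    n_lambda = len(wavelengths)
    nx, ny = d_map.shape

    # smooth waveform: random low-order Fourier series along wavelength,
    # per pixel, standardized exactly (zero mean, unit sample sd, ddof=1)
    t = np.arange(n_lambda)[:, None, None] / n_lambda
    wave = np.zeros((n_lambda, nx, ny))
    for cycles in (1, 2, 3, 4):
        amp = rng.normal(size=(nx, ny))
        phase = rng.uniform(0, 2 * np.pi, size=(nx, ny))
        wave += amp * np.cos(2 * np.pi * cycles * t + phase)
    wave -= wave.mean(axis=0)
    sd = wave.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    wave /= sd

    sigma_target = np.asarray(calib.forward(d_map), dtype=float)
    normalized = 1.0 + sigma_target * wave
    if noise_sd > 0:
        normalized = normalized + rng.normal(0.0, noise_sd, size=normalized.shape)
    reference = np.full((n_lambda, nx, ny), reference_level)
    intensities = np.clip(normalized, 0.0, None) * reference
    return SpectralCube(intensities, np.asarray(wavelengths, float), reference)


def gen_nucleus_cohort(
    cfg: SimConfig,
) -> tuple[dict[str, list[tuple[SpectralCube, np.ndarray]]], pd.DataFrame]:
    """Cohort of single-nucleus cubes with circular masks, one per nucleus.

    Each nucleus in group g has a true nuclear packing scaling drawn from
    N(true_dn_means[g], true_dn_sd), painted uniformly inside its mask.
    Returns {group: [(cube, mask), ...]} and a truth table
    (group, nucleus, true_dn).
    """
    rng = _rng(cfg.seed)
    calib = cfg.calibration()
    _, nx, ny = cfg.cube_shape
    yy, xx = np.mgrid[0:nx, 0:ny]
    mask = (xx - ny / 2) ** 2 + (yy - nx / 2) ** 2 <= (min(nx, ny) / 3) ** 2
    lo, hi = calib.domain
    cohort: dict[str, list[tuple[SpectralCube, np.ndarray]]] = {}
    truth_rows = []
    for group, mean in cfg.true_dn_means.items():
        nuclei = []
        for i in range(cfg.n_nuclei_per_group):
            true_dn = float(
                np.clip(rng.normal(mean, cfg.true_dn_sd), lo + 0.05, hi - 0.05)
            )
            d_map = np.full((nx, ny), true_dn)
            noise_sd = cfg.noise_frac * float(calib.forward(true_dn))
            cube = gen_pws_cube(
                d_map,
                mask,
                calib,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
                wavelengths=cfg.wavelengths,
            )
            nuclei.append((cube, mask))
            truth_rows.append({"group": group, "nucleus": i, "true_dn": true_dn})
        cohort[group] = nuclei
    return cohort, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bulk expression
# ---------------------------------------------------------------------------

def gen_bulk_expression(cfg: SimConfig) -> tuple[ExpressionTable, pd.DataFrame]:
    """Two-condition x two-cell-type count table with planted LFC structure.

    Gene baseline means span four decades (log-uniform); counts are
    negative binomial with constant dispersion.  Genes in the lowest
    baseline decile are planted responders: in the CSC-like cell type
    (ALDH+) their log2 fold change under treatment is a symmetric
    two-component mixture at +/- ``lfc_mu`` (a bimodal up-and-down
    response); in the non-CSC-like type (ALDH-) the same genes respond
    with a single positive-mean component.  All other genes carry
    small-scale background LFC noise.

    Returns the counts table (with lengths, metadata, and leading ERCC
    spike-in rows to exercise cleaning) and a per-gene truth table.
    """
    if cfg.n_genes < 100:
        raise ValueError("n_genes must be >= 100 for non-degenerate deciles")
    rng = _rng(cfg.seed + 1)
    n = cfg.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    means = 10 ** rng.uniform(np.log10(50), np.log10(500_000), size=n)
    lengths = np.round(10 ** rng.uniform(np.log10(500), np.log10(100_000), size=n))

    decile_cut = np.quantile(means, 0.1)
    planted = means <= decile_cut

    w_hi = cfg.lfc_mixture_weights[0]
    up = rng.random(size=n) < w_hi
    lfc_csc = np.where(
        planted,
        np.where(up, cfg.lfc_mu, -cfg.lfc_mu)
        + rng.normal(0, cfg.lfc_component_sd, size=n),
        rng.normal(0, cfg.lfc_background_sd, size=n),
    )
    lfc_ncsc = np.where(
        planted,
        cfg.lfc_mu + rng.normal(0, cfg.lfc_component_sd, size=n),
        rng.normal(0, cfg.lfc_background_sd, size=n),
    )

    size = 1.0 / cfg.dispersion  # NB shape parameter

    def nb(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(size, size / (size + mu))

    columns, meta = {}, []
    for cell_type, lfc in (("ALDH+", lfc_csc), ("ALDH-", lfc_ncsc)):
        for treatment, mu in (
            ("control", means),
            ("cisplatin", means * np.power(2.0, lfc)),
        ):
            for rep in range(1, cfg.n_replicates + 1):
                name = f"{cell_type}_{treatment}_r{rep}"
                columns[name] = nb(mu)
                meta.append(
                    {
                        "sample": name,
                        "cell_type": cell_type,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    length_s = pd.Series(lengths, index=values.index, name="length")

    # ERCC spike-ins: constant abundance, removed by cleaning
    if cfg.n_ercc:
        ercc_ids = [f"ERCC-{i:05d}" for i in range(cfg.n_ercc)]
        ercc = pd.DataFrame(
            {c: nb(np.full(cfg.n_ercc, 1000.0)) for c in values.columns},
            index=pd.Index(ercc_ids, name="gene_id"),
        )
        values = pd.concat([ercc, values])
        length_s = pd.concat(
            [pd.Series(1000.0, index=ercc.index, name="length"), length_s]
        )

    table = ExpressionTable(
        values=values,
        lengths=length_s,
        samples=pd.DataFrame(meta).set_index("sample"),
        unit="counts",
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_mean": means,
            "planted_low_decile": planted,
            "lfc_csc": lfc_csc,
            "lfc_ncsc": lfc_ncsc,
        }
    ).set_index("gene_id")
    return table, truth


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def gen_embedding(
    n: int,
    sigma: float | np.ndarray = 1.0,
    seed: int = 0,
    condition: str = "sim",
) -> Embedding:
    """n iid points from an isotropic (or per-axis) 3D Gaussian."""
    if n < 2:
        raise ValueError("need n >= 2 points")
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (3,))
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    rng = _rng(seed)
    pts = rng.normal(0.0, 1.0, size=(n, 3)) * sigma
    cells = [f"cell{i}" for i in range(n)]
    return Embedding(
        pd.DataFrame(pts, index=cells, columns=["x", "y", "z"]),
        pd.Series(condition, index=cells),
    )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _partition_total(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` bp into k positive integer parts, uniformly at random."""
    if k == 1:
        return np.array([total], dtype=np.int64)
    cuts = np.sort(rng.choice(total - 1, size=k - 1, replace=False) + 1)
    edges = np.concatenate(([0], cuts, [total]))
    return np.diff(edges).astype(np.int64)


def _partition_gaps(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` bp into k nonnegative integer parts."""
    cuts = np.sort(rng.integers(0, total + 1, size=k - 1)) if k > 1 else np.array([], int)
    edges = np.concatenate(([0], cuts, [total]))
    return np.diff(edges).astype(np.int64)


def gen_peaks(
    cfg: SimConfig,
    target_densities: dict[tuple[str, str], float],
    peaks_per_chrom: int = 10,
) -> dict[str, PeakSet]:
    """Peak sets whose merged per-chromosome bp density hits given targets.

    ``target_densities`` maps (chrom, mark) to a fraction in [0, 1]; the
    generated intervals per chromosome are sorted and non-overlapping and
    their total length equals ``round(density * chrom_length)`` exactly
    (within 1 bp of the requested density).
    """
    rng = _rng(cfg.seed + 2)
    marks = sorted({mark for (_, mark) in target_densities})
    out: dict[str, list[dict]] = {m: [] for m in marks}
    for (chrom, mark), density in sorted(target_densities.items()):
        if not 0.0 <= density <= 1.0:
            raise ValueError(f"density {density} outside [0, 1] for {chrom}/{mark}")
        length = cfg.chrom_sizes[chrom]
        total = int(round(density * length))
        if total == 0:
            continue
        k = max(1, min(peaks_per_chrom, total))
        widths = _partition_total(total, k, rng)
        gaps = _partition_gaps(length - total, k + 1, rng)
        pos = 0
        for gap, width in zip(gaps[:-1], widths):
            start = pos + int(gap)
            out[mark].append(
                {"chrom": chrom, "start": start, "end": start + int(width)}
            )
            pos = start + int(width)
    result = {}
    for mark in marks:
        df = pd.DataFrame(out[mark], columns=["chrom", "start", "end"])
        result[mark] = PeakSet(mark, df)
    return result


def gen_correlated_densities(
    cfg: SimConfig,
    marks: tuple[str, str] = ("H3K4me3", "H3K27me3"),
    mean: float = 0.15,
    sd: float = 0.03,
    seed: int | None = None,
) -> dict[tuple[str, str], float]:
    """Per-autosome density targets for two marks, correlated at planted_rho.

    Densities are drawn from a bivariate normal with the configured
    correlation and clipped to (0.001, 0.999); with the default mean/sd the
    clip is essentially never active, so the sample correlation structure
    is preserved.
    """
    rng = _rng(cfg.seed + 3 if seed is None else seed)
    autosomes = [c for c in cfg.chrom_sizes if c != "chrX"]
    rho = cfg.planted_rho
    cov = np.array([[1.0, rho], [rho, 1.0]]) * sd**2
    draws = rng.multivariate_normal([mean, mean], cov, size=len(autosomes))
    draws = np.clip(draws, 0.001, 0.999)
    targets = {}
    for i, chrom in enumerate(autosomes):
        targets[(chrom, marks[0])] = float(draws[i, 0])
        targets[(chrom, marks[1])] = float(draws[i, 1])
    return targets


# ---------------------------------------------------------------------------
# annotation with planted bivalent promoters
# ---------------------------------------------------------------------------

def _window_hits(
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom: str,
    pos: int,
    window: int,
) -> bool:
    """Does any merged interval of this mark overlap [pos-window, pos+window)?"""
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    if starts.size == 0:
        return False
    lo, hi = pos - window, pos + window
    i = np.searchsorted(starts, hi)  # intervals with start < hi
    return bool(i > 0 and np.any(ends[:i] > lo))


def gen_annotation(
    cfg: SimConfig,
    marks: dict[str, PeakSet],
    n_genes: int = 50,
    window: int = 2000,
    candidate_step: int = 500,
) -> GeneAnnotation:
    """Gene annotation in which exactly the planted genes are bivalent.

    TSS positions are chosen so that every gene in ``cfg.planted_poised``
    has at least one H3K4me3 and one H3K27me3 peak within ``window`` bp of
    its TSS, and every other gene has at most one of the two marks in its
    window.  Gene ids are g1..gN; planted ids must be a subset of those.
    """
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    unknown = cfg.planted_poised - set(gene_ids)
    if unknown:
        raise ValueError(f"planted poised genes outside g1..g{n_genes}: {sorted(unknown)}")
    if "H3K4me3" not in marks or "H3K27me3" not in marks:
        raise ValueError("need H3K4me3 and H3K27me3 peak sets")

    merged: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for mark in ("H3K4me3", "H3K27me3"):
        merged[mark] = {}
        for chrom, sub in marks[mark].intervals.groupby("chrom"):
            merged[mark][chrom] = merge_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy()
            )

    both_sites: list[tuple[str, int]] = []
    mono_sites: list[tuple[str, int]] = []
    for chrom, length in cfg.chrom_sizes.items():
        if length < 2 * window + candidate_step:
            raise ValueError(f"chromosome {chrom} too short to place genes")
        for pos in range(window, length - window, candidate_step):
            k4 = _window_hits(merged["H3K4me3"], chrom, pos, window)
            k27 = _window_hits(merged["H3K27me3"], chrom, pos, window)
            if k4 and k27:
                both_sites.append((chrom, pos))
            else:
                mono_sites.append((chrom, pos))

    n_poised = len(cfg.planted_poised)
    n_other = n_genes - n_poised
    if len(both_sites) < n_poised or len(mono_sites) < n_other:
        raise ValueError(
            "not enough candidate TSS sites: "
            f"{len(both_sites)} bivalent (need {n_poised}), "
            f"{len(mono_sites)} other (need {n_other})"
        )
    rng = _rng(cfg.seed + 4)
    both_pick = [both_sites[i] for i in rng.choice(len(both_sites), n_poised, replace=False)]
    mono_pick = [mono_sites[i] for i in rng.choice(len(mono_sites), n_other, replace=False)]

    rows = []
    poised_sorted = sorted(cfg.planted_poised)
    others = [g for g in gene_ids if g not in cfg.planted_poised]
    for gene, (chrom, pos) in zip(poised_sorted + others, both_pick + mono_pick):
        rows.append(
            {
                "gene_id": gene,
                "chrom": chrom,
                "strand": "+" if rng.random() < 0.5 else "-",
                "tss": pos,
            }
        )
    rows.sort(key=lambda r: gene_ids.index(r["gene_id"]))
    return GeneAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

def gen_single_cell(
    cfg: SimConfig,
    n_genes: int = 500,
    n_mito_genes: int = 10,
    n_fail_low_reads: int = 3,
    n_fail_high_reads: int = 3,
    n_fail_mito: int = 2,
    n_fail_features: int = 2,
    library_mean_log: float = np.log(50_000),
    library_sd_log: float = 0.2,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Single-cell count matrix with planted QC failures.

    Library sizes for passing cells follow a log-normal (clipped well
    inside the 20k-100k window); planted failing cells violate exactly one
    rule each, with wide margins so multinomial sampling noise never flips
    a label: low/high read counts, mitochondrial fraction >= 15% ("MT"
    prefixed genes), or fewer than 200 detected features.  Returns the
    matrix and a per-cell truth table (library, planted failure mode,
    expected QC pass).
    """
    n_fail = n_fail_low_reads + n_fail_high_reads + n_fail_mito + n_fail_features
    if n_fail > cfg.n_cells:
        raise ValueError("more planted failures than cells")
    if n_genes <= 250:
        raise ValueError("need > 250 genes so passing cells clear the feature floor")
    rng = _rng(cfg.seed + 5)
    mito_ids = [f"MT-{i}" for i in range(n_mito_genes)]
    other_ids = [f"sc_gene{i:04d}" for i in range(n_genes - n_mito_genes)]
    gene_ids = mito_ids + other_ids

    base_props = rng.dirichlet(np.full(n_genes, 5.0))
    # passing cells: ~5% mitochondrial reads
    props_pass = base_props.copy()
    props_pass[:n_mito_genes] *= 0.05 / props_pass[:n_mito_genes].sum()
    props_pass[n_mito_genes:] *= 0.95 / props_pass[n_mito_genes:].sum()
    # mito-failing cells: ~30% mitochondrial reads
    props_mito = base_props.copy()
    props_mito[:n_mito_genes] *= 0.30 / props_mito[:n_mito_genes].sum()
    props_mito[n_mito_genes:] *= 0.70 / props_mito[n_mito_genes:].sum()
    # feature-failing cells: all reads on the first 150 non-mito genes
    props_feat = np.zeros(n_genes)
    props_feat[n_mito_genes : n_mito_genes + 150] = 1.0 / 150

    modes = (
        ["low_reads"] * n_fail_low_reads
        + ["high_reads"] * n_fail_high_reads
        + ["mito"] * n_fail_mito
        + ["features"] * n_fail_features
        + ["pass"] * (cfg.n_cells - n_fail)
    )
    rng.shuffle(modes)
    rows, truth = [], []
    for i, mode in enumerate(modes):
        if mode == "low_reads":
            lib = int(rng.integers(5_000, 15_000))
            props = props_pass
        elif mode == "high_reads":
            lib = int(rng.integers(120_000, 200_000))
            props = props_pass
        elif mode == "mito":
            lib = int(rng.integers(30_000, 80_000))
            props = props_mito
        elif mode == "features":
            lib = int(rng.integers(30_000, 80_000))
            props = props_feat
        else:
            lib = int(
                np.clip(rng.lognormal(library_mean_log, library_sd_log), 25_000, 90_000)
            )
            props = props_pass
        rows.append(rng.multinomial(lib, props))
        truth.append(
            {"cell": f"c{i:03d}", "library": lib, "mode": mode, "qc_pass": mode == "pass"}
        )
    counts = pd.DataFrame(
        np.array(rows), index=[t["cell"] for t in truth], columns=gene_ids
    )
    return CellMatrix(counts, mito_prefix="MT"), pd.DataFrame(truth).set_index("cell")


def gen_condition_embeddings(
    spreads: dict[str, float], n_per_condition: int = 200, seed: int = 0
) -> tuple[Embedding, dict[str, float]]:
    """Multi-condition embedding with planted per-condition spread.

    Each condition is an isotropic 3D Gaussian of the given per-axis sd,
    centered apart; the planted RMS radius of condition c is
    sigma_c * sqrt(3 (n-1)/n).
    """
    rng = _rng(seed)
    frames, labels = [], []
    truth = {}
    for j, (cond, sigma) in enumerate(sorted(spreads.items())):
        pts = rng.normal(0.0, sigma, size=(n_per_condition, 3)) + j * 100.0
        cells = [f"{cond}_cell{i}" for i in range(n_per_condition)]
        frames.append(pd.DataFrame(pts, index=cells, columns=["x", "y", "z"]))
        labels.append(pd.Series(cond, index=cells))
        truth[cond] = sigma * np.sqrt(3.0 * (n_per_condition - 1) / n_per_condition)
    return Embedding(pd.concat(frames), pd.concat(labels)), truth
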