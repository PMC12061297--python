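"""Intracellular transcriptional plasticity analysis of bulk RNA-seq.

Quantifies how strongly genes respond to a stressor (e.g. cisplatin) as a
function of their baseline expression, the signature used to contrast
cancer-stem-cell (ALDH+) plasticity with ALDH- bulk cells:

1. counts -> TPM (length- and depth-normalized),
2. cleaning: drop ERCC spike-ins and NaN genes, renormalize each sample to
   1e6, drop genes with a zero in any sample, average replicates,
3. gate genes at |log2 fold change| >= 1 between baseline and stressor,
4. baseline-quantile response curves (mean change per baseline decile), and
5. lowest-baseline-decile log2FC distributions summarized by a Gaussian KDE
   and the sample bimodality coefficient (the finite-sample form of
   b = (skew^2 + 1) / kurtosis).

A bimodality coefficient above 0.555 (the value for a uniform distribution)
flags a bimodal up-and-down response; a unimodal shifted response stays
below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

BIMODALITY_THRESHOLD = 5.0 / 9.0  # uniform-distribution reference value


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene x sample expression with per-sample metadata.

    ``values``: DataFrame indexed by gene_id, one column per sample.
    ``lengths``: per-gene length in bp (same index), needed for TPM.
    ``samples``: DataFrame indexed by sample name with columns
    cell_type, treatment, replicate.
    """

    values: pd.DataFrame
    lengths: pd.Series | None = None
    samples: pd.DataFrame | None = None
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if (self.lengths <= 0).any() or self.lengths.isna().any():
                raise ValueError("gene lengths must be positive for all genes")
        if self.samples is not None:
            missing = set(self.values.columns) - set(self.samples.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")

    def sample_names(self, cell_type: str, treatment: str) -> list[str]:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        sel = (self.samples["cell_type"] == cell_type) & (
            self.samples["treatment"] == treatment
        )
        return self.samples.index[sel].tolist()


@dataclass
class PlasticityResult:
    """Baseline-quantile response curve and lowest-decile LFC summaries."""

    curve: pd.DataFrame              # quantile, mean_baseline, mean_delta, sem, n_genes
    lowest_decile_genes: list[str]
    lfc: dict[str, pd.Series]        # group label -> per-gene LFC
    kde_summary: dict[str, dict]     # group label -> mean/sd/bimodality/kde grid


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: reads per base, scaled to 1e6 per sample.

    TPM_g = (count_g / length_g) / sum_g'(count_g' / length_g') * 1e6, so
    every column sums to exactly 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total rate in samples: {zero.index.tolist()}")
    return rate.div(totals, axis=1) * 1e6


def clean_expression(
    tpm: ExpressionTable, ercc_prefix: str = "ERCC-"
) -> tuple[ExpressionTable, dict]:
    """Clean a TPM table in a fixed order and average replicates.

    Order: (1) drop ERCC spike-in identifiers and genes with any NaN,
    (2) renormalize each sample to sum 1e6, (3) drop genes with a zero
    value in any sample, (4) average replicates within each
    (cell_type, treatment) condition.

    Returns the cleaned table (columns = "celltype|treatment") and an
    attrition report with per-stage removal counts.
    """
    if tpm.samples is None:
        raise ValueError("replicate structure (sample metadata) required")
    values = tpm.values
    n_input = len(values)

    is_ercc = values.index.str.startswith(ercc_prefix)
    has_nan = values.isna().any(axis=1)
    values = values[~is_ercc & ~has_nan]
    n_after_ercc_nan = len(values)

    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total after ERCC/NaN removal")
    values = values.div(totals, axis=1) * 1e6

    has_zero = (values == 0).any(axis=1)
    values = values[~has_zero]
    n_after_zero = len(values)
    if n_after_zero == 0:
        raise ValueError(
            "all genes removed during cleaning: "
            f"input={n_input}, ercc={int(is_ercc.sum())}, "
            f"nan={int(has_nan.sum())}, zero={int(has_zero.sum())}"
        )

    meta = tpm.samples
    conditions = meta.groupby(["cell_type", "treatment"], sort=False).groups
    averaged = pd.DataFrame(index=values.index)
    cond_meta = []
    for (cell_type, treatment), sample_idx in conditions.items():
        cols = [s for s in sample_idx if s in values.columns]
        label = f"{cell_type}|{treatment}"
        averaged[label] = values[cols].mean(axis=1)
        cond_meta.append(
            {"sample": label, "cell_type": cell_type, "treatment": treatment,
             "replicate": "mean"}
        )
    report = {
        "input_genes": n_input,
        "removed_ercc": int(is_ercc.sum()),
        "removed_nan": int((has_nan & ~is_ercc).sum()),
        "removed_zero": int(has_zero.sum()),
        "removed_total": n_input - n_after_zero,
        "surviving_genes": n_after_zero,
    }
    cleaned = ExpressionTable(
        values=averaged,
        samples=pd.DataFrame(cond_meta).set_index("sample"),
        unit="tpm_cleaned",
    )
    return cleaned, report


def lfc_gate(
    baseline: pd.Series,
    treated: pd.Series,
    min_abs_lfc: float = 1.0,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Log2 fold change treated/baseline, retaining |LFC| >= min_abs_lfc.

    Cleaned TPM is zero-free so the default pseudocount is 0; a positive
    pseudocount is available for robustness on uncleaned user data.
    """
    baseline, treated = baseline.align(treated, join="inner")
    if pseudocount == 0.0 and ((baseline <= 0).any() or (treated <= 0).any()):
        raise ValueError(
            "zero or negative expression present; clean first or use a pseudocount"
        )
    lfc = np.log2((treated + pseudocount) / (baseline + pseudocount))
    out = pd.DataFrame(
        {"baseline": baseline, "treated": treated, "lfc": lfc}
    )
    return out[lfc.abs() >= min_abs_lfc]


def quantile_response(
    baseline: pd.Series, treated: pd.Series, n_quantiles: int = 10
) -> pd.DataFrame:
    """Mean expression change per baseline-expression quantile with SEM.

    Genes are ranked by baseline expression (ties broken by stable gene-id
    order) and split into ``n_quantiles`` near-equal bins; per bin the mean
    baseline (x), mean delta = treated - baseline (y) and its standard
    error are reported.
    """
    if n_quantiles < 2:
        raise ValueError("need at least 2 quantiles")
    baseline, treated = baseline.align(treated, join="inner")
    if len(baseline) < n_quantiles:
        raise ValueError("fewer genes than quantiles")
    order = baseline.sort_values(kind="stable").index
    bins = np.array_split(np.arange(len(order)), n_quantiles)
    rows = []
    for q, idx in enumerate(bins):
        genes = order[idx]
        delta = treated.loc[genes] - baseline.loc[genes]
        sem = float(delta.std(ddof=1) / np.sqrt(len(delta))) if len(delta) > 1 else 0.0
        rows.append(
            {
                "quantile": q + 1,
                "mean_baseline": float(baseline.loc[genes].mean()),
                "mean_delta": float(delta.mean()),
                "sem": sem,
                "n_genes": len(genes),
            }
        )
    return pd.DataFrame(rows)


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sample bimodality coefficient with the finite-sample kurtosis correction.

    b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3))), with g1 the
    bias-corrected sample skewness and g2 the bias-corrected sample excess
    kurtosis.  As n grows this converges to (skew^2 + 1) / kurtosis; the
    correction term matters at the decile sizes (~30 genes) this is applied
    to, where the uncorrected ratio is biased upward and over-calls
    bimodality in unimodal samples.  b exceeds 5/9 (the uniform reference)
    for distributions flatter or more two-horned than the uniform.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 observations for a bimodality coefficient")
    g1 = _stats.skew(x, bias=False)
    g2 = _stats.kurtosis(x, fisher=True, bias=False)
    correction = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g1**2 + 1.0) / (g2 + correction))


def lowest_decile_lfc(
    cleaned: ExpressionTable,
    source_group: tuple[str, str],
    response_pairs: dict[str, tuple[tuple[str, str], tuple[str, str]]],
    min_abs_lfc: float = 1.0,
    n_quantiles: int = 10,
    kde_grid_size: int = 512,
) -> PlasticityResult:
    """LFC distributions, in several groups, of the source group's weakest genes.

    The gene set is defined in ``source_group`` (a cleaned (cell_type,
    treatment) condition): among genes passing the |LFC| gate between the
    source cell type's baseline and stressor condition, those in the lowest
    baseline-expression decile are extracted.  For each entry of
    ``response_pairs`` (label -> (baseline condition, treated condition)),
    the log2 fold change of exactly those genes is computed and summarized
    by mean, sd, bimodality coefficient, and a Gaussian KDE (Scott
    bandwidth) evaluated on a fixed grid.
    """
    def col(cond: tuple[str, str]) -> pd.Series:
        label = f"{cond[0]}|{cond[1]}"
        if label not in cleaned.values.columns:
            raise ValueError(f"condition {label!r} not in cleaned table")
        return cleaned.values[label]

    source_baseline = col(source_group)
    # gate within the source cell type: baseline vs its stressor pair
    source_pair = next(
        (pair for pair in response_pairs.values() if pair[0] == source_group),
        None,
    )
    if source_pair is None:
        raise ValueError("response_pairs must include the source group's own pair")
    gated = lfc_gate(col(source_pair[0]), col(source_pair[1]), min_abs_lfc)
    if gated.empty:
        raise ValueError("no genes survive the fold-change gate")

    ranked = source_baseline.loc[gated.index].sort_values(kind="stable")
    decile_size = int(np.ceil(len(ranked) / n_quantiles))
    lowest = ranked.index[:decile_size].tolist()
    if not lowest:
        raise ValueError("lowest decile empty after gating")

    lfc, kde_summary = {}, {}
    for label, (base_cond, treat_cond) in response_pairs.items():
        vals = np.log2(col(treat_cond).loc[lowest] / col(base_cond).loc[lowest])
        lfc[label] = vals
        grid = np.linspace(vals.min() - 1.0, vals.max() + 1.0, kde_grid_size)
        if vals.std(ddof=0) > 0 and len(vals) > 3:
            kde = _stats.gaussian_kde(vals.to_numpy(), bw_method="scott")
            density = kde(grid)
            b = bimodality_coefficient(vals.to_numpy())
        else:
            density = np.zeros_like(grid)
            b = float("nan")
        kde_summary[label] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "bimodality_coefficient": b,
            "bimodal": bool(b > BIMODALITY_THRESHOLD) if np.isfinite(b) else None,
            "grid": grid,
            "density": density,
            "n_genes": int(len(vals)),
        }

    curve = quantile_response(
        col(source_pair[0]).loc[gated.index],
        col(source_pair[1]).loc[gated.index],
        n_quantiles,
    )
    return PlasticityResult(
        curve=curve,
        lowest_decile_genes=lowest,
        lfc=lfc,
        kde_summary=kde_summary,
    )


def count_kde_modes(grid: np.ndarray, density: np.ndarray, rel_height: float = 0.05) -> int:
    """Count local maxima of a KDE curve above a fraction of the global peak."""
    peak = density.max()
    is_max = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    strong = density[1:-1] > rel_height * peak
    return int(np.sum(is_max & strong))
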