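# Methods

This note documents the models, parameter choices and numerical decisions
behind `chromoplast`, and what the synthetic validation does and does not
demonstrate about real data.

## PWS spectral-cube analysis

A PWS acquisition is a cube *I*(λ, *x*, *y*) on a 515–685 nm grid at 2 nm
(86 planes) with a same-shape cell-free reference cube. The analysis chain
is: zero-phase Butterworth low-pass along λ → per-pixel division by the
reference → per-pixel sample standard deviation σ(*x*, *y*) over λ →
calibration inversion to the local packing scaling *D*<sub>a</sub>(*x*, *y*)
→ arithmetic mean over the nuclear mask, *D*<sub>n</sub>.

**Calibration.** The quantitative σ ↔ *D* relation depends on the
instrument's optical parameters and on the assumed chromatin density
autocorrelation function, and is deliberately *not* hard-coded. The
package ships a pluggable `CalibrationModel` — strictly monotone on an
open domain, default (1, 3) — with two families: linear σ = *b*(*D* − 1)
(default, *b* = 0.05) and power σ = *a*(*D* − 1)<sup>*c*</sup>. Every
contract the pipeline relies on (round trip to 1e−9 on a domain grid,
monotonicity, clipping semantics) is family-independent. Absolute
*D*-values on real cubes are only as good as the supplied calibration;
group *differences* and normalized means are robust to monotone
miscalibration. Pixels whose inverted *D* falls outside the domain are
clipped to the domain edge and counted in a QC report rather than dropped,
so nuclear averages keep their pixel counts.

**Filtering.** Butterworth defaults: order 2, cutoff 0.2 cycles/sample,
applied forward–backward (`sosfiltfilt`) so the passband is zero-phase and
DC gain is exactly 1. The cutoff sits well above the 1–4 cycles-per-cube
interference structure the σ statistic measures and well below the white
LED noise it suppresses; both are configurable.

**Masks.** Nuclear masks are supplied explicitly (the normal path, matching
manually drawn ROIs) or derived as a fallback by Otsu thresholding of the
mean-intensity image.

**Population comparison.** Per-group *D*<sub>n</sub> lists are compared to
a control group with Welch's unequal-variance *t*-test; significance uses
the Bonferroni-style threshold α = 0.05/*N*, *N* the number of groups.
Group means are also reported normalized to the control mean (control ≡ 1).

## Synthetic spectra

`gen_pws_cube` inverts the measurement model: each pixel's normalized
spectrum is 1 + σ·*w*(λ) with *w* a random 1–4-cycle Fourier waveform
standardized to exactly zero mean and unit sample sd, so with zero noise
the measured spectral sd equals `calib.forward(D)` to machine precision.
Measurement noise is additive white Gaussian on the normalized intensity
(default sd 5% of the signal σ) — the simplest model that preserves the
σ-encoding contract and gives the low-pass filter something real to
remove. The generator does not model optics (point-spread functions,
coherence volumes, shot-noise statistics); recovery results therefore
validate the analysis chain, not the microscope.

Cohort defaults are the study conditions used throughout the tests:
30 nuclei/group, true *D*<sub>n</sub> ~ N(2.34, 0.1) for the CSC-like and
N(2.05, 0.1) for the non-CSC-like group, 86×24×24 cubes.

## Bulk transcriptional plasticity

Counts are converted to TPM (reads per base scaled to 10⁶ per sample), then
cleaned in a fixed order: (1) drop ERCC spike-ins and NaN genes,
(2) renormalize each sample to 10⁶, (3) drop genes with a zero in any
sample, (4) average replicates per condition. The order matters: zero
removal after renormalization means condition columns are no longer exactly
10⁶ afterwards, which is intended — the renormalization stage, not the
final table, carries the conservation guarantee. Log₂ fold changes are
computed on the zero-free cleaned table, so no pseudocount is needed
(one is available, default 0, for uncleaned user data). The |LFC| ≥ 1 gate
is applied to *genes*; the configurable threshold defaults to 1.

The response curve bins genes into baseline-expression deciles by rank
(stable gene-id tie-break; bin sizes differ by ≤ 1) and reports mean
baseline, mean Δexpression and SEM per bin. Δ is expression difference by
default with an LFC option, since either reading is defensible; the choice
only rescales the y-axis, not the decile structure.

The lowest-decile analysis takes the genes in the lowest baseline decile
of the source condition (among gated genes) and summarizes their LFC in
each requested condition pair by mean, sd, a Gaussian KDE (Scott bandwidth,
512-point grid) and the sample bimodality coefficient

  b = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3))),

with g₁/g₂ the bias-corrected sample skewness/excess kurtosis and 5/9 (the
uniform distribution's value) as the bimodal threshold. The finite-sample
kurtosis correction is essential here: at the ~30-gene decile sizes this
analysis produces, the asymptotic ratio (skew² + 1)/kurtosis is biased
upward and calls ~7% of genuinely unimodal samples bimodal.

The generator plants the contrast the analysis is meant to detect: genes in
the lowest baseline decile respond with a symmetric ± μ two-component LFC
mixture (μ = 2, 50/50, component sd 0.25) in the CSC-like cell type and a
single positive-mean component in the non-CSC-like type; background genes
carry N(0, 0.2) LFC noise. Counts are negative binomial (dispersion 0.1)
with gene means log-uniform over four decades (50–5·10⁵) so decile binning
is non-degenerate. At these conditions the bimodal/unimodal classification
plus the sd ordering is recovered in ≈ 98% of seeded runs; the residue is
counting noise at low expression, which also lets a small number of
null genes through the |LFC| gate (≈ 3% of genes when no effect is
planted).

## Single-cell heterogeneity

QC follows standard thresholds with exact boundary semantics: genes kept if
detected in ≥ 3 cells (applied first), cells removed if reads < 20 000 or
> 100 000 (both bounds keep the boundary value), mitochondrial fraction
≥ 0.15 ("MT"-prefixed genes; 15% *is* removed), or detected features
< 200. The report attributes each removed cell to every rule it violates.

Normalization is ln(1 + count/total · 10⁴). Variable genes are ranked by
variance standardized against a rank-based running-median mean–variance
trend (window 51) — a loess-free variance-stabilizing selection; selected
genes are z-scaled with clipping at ± 10. PCA is exact SVD with a
deterministic sign convention (largest-|loading| coefficient positive);
dimensions 1–20 feed the 3D embedding.

The 3D embedding is a pluggable contract (any PC-matrix → ℝ³ function; a
3D t-SNE in typical use). The shipped default is the deterministic
first-three-PCs projection so that results and tests never depend on a
stochastic, seed-fragile embedder. The radius of genomic space is
*R*<sub>c</sub> = √(1/*N* Σ‖*r*ᵢ − *r̄*‖²) per condition — an RMS radius,
invariant to rigid motions and linear in global scale; for *n* iid
isotropic Gaussian points E[*R*<sub>c</sub>²] = 3σ²(*n* − 1)/*n*. Unequal
condition sizes are handled by `equalize`: `subsample` (default, seeded
down-sampling to the smallest condition), `weights` (uniform per-cell
weights 1/N in mean and sum, the analytic counterpart of subsampling — for
a per-condition statistic this coincides with the unweighted value and is
reported for transparency), or `none`. The bounding-sphere reading of a
"radius containing all cells" is deliberately not implemented; the RMS
formula governs.

## Chromatin-mark analytics

Coordinates are 0-based half-open (BED dialect) throughout. Overlapping
peaks are merged before any bp summation so per-chromosome density
Σ bp/chrom-length is guaranteed ≤ 1 and merging is idempotent; chrX is
excluded from density analyses by default (distinct heterochromatin
mechanics). Cross-mark regression is OLS of one mark's densities on the
other's across shared chromosomes (≥ 3 required), with *R*² the squared
Pearson correlation; a flat response returns *R*² = 0 exactly.

Differential gating retains peaks with strict *p* < p_max, default 0.1,
configurable down to adjusted-*p* style 0.05 — both conventions appear in
practice and neither is asserted as uniquely correct.

Poised (bivalent) calling associates a peak with a gene iff it overlaps the
half-open promoter window [TSS − 2000, TSS + 2000) by ≥ 1 bp, strand
ignored, peaks allowed to hit several genes; a gene is poised when it has
≥ 1 H3K4me3 and ≥ 1 H3K27me3 peak in the window. Peak feature annotation
classifies by peak midpoint with fixed priority promoter > exon > intron >
intergenic. Promoter signal matrices average bedGraph coverage in 50-bp
bins over ± 2 kb, take log₂((A + 1)/(B + 1)), and reverse minus-strand rows
so bins run 5'→3'; clustering is K-means (K = 6, k-means++, 10 restarts,
fixed seed, Lloyd).

The peak generator constructs sorted non-overlapping intervals whose total
length equals round(density · length) exactly (≤ 1 bp from the requested
density); per-autosome densities for two marks are drawn bivariate normal
(mean 0.15, sd 0.03, correlation 0.82 by default — the regime in which the
22-autosome regression *R*² averages ≈ ρ² ≈ 0.67). The annotation
generator places TSSs on a 500-bp candidate grid so that exactly the
planted genes are bivalent and all others carry at most one mark in their
window.

## Validation scale and limitations

The acceptance runs use the cohort sizes above (60 nuclei, 2 000-gene bulk
tables, 100-cell matrices, 22 autosomes × 500 replicates, 200 plasticity
cohorts), chosen as the smallest sizes at which every planted effect is
comfortably resolvable. The generators emulate the *structure* of each
input, not its full biology: no sequencing-read simulation, no realistic
genome sequence, no optics, no batch effects, and single-dispersion
negative-binomial counts. Passing tests therefore demonstrate that the
analysis chain recovers known truth under its own measurement models, not
that any biological conclusion transfers to a particular dataset. Absolute
*D*<sub>n</sub> values on real cubes additionally require an
instrument-specific calibration.
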