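# chromoplast

Analytics linking nanoscale chromatin packing to the transcriptional
plasticity of cancer stem cells (CSCs). Ovarian-cancer CSCs (ALDH+
flow-sorted cells) differ from ALDH− bulk cells in how densely their
chromatin is packed into nanoscale domains, how many of their promoters sit
in a poised bivalent state, and how heterogeneously and flexibly they
transcribe under chemotherapy stress. `chromoplast` implements the four
quantitative analyses needed to measure those differences, plus a
synthetic-data generator so every stage can be validated end to end against
planted ground truth:

- **PWS image analysis** (`chromoplast.pws`). Partial wave spectroscopic
  microscopy records a cube *I*(λ, *x*, *y*) of backscattered intensity
  (515–685 nm, 2 nm steps) plus a cell-free reference cube. After a
  zero-phase Butterworth low-pass along λ and reference normalization, the
  per-pixel spectral standard deviation σ(*x*, *y*) encodes nanoscale
  chromatin density fluctuations. A strictly monotone calibration maps σ to
  the local chromatin packing scaling *D*<sub>a</sub>(*x*, *y*) (from the
  mass-fractal relation *N* ∼ *R*<sup>*D*</sup>); its nuclear average is
  *D*<sub>n</sub>. Populations are compared with Welch's unequal-variance
  *t*-test at α = 0.05/*N* groups.
- **Transcriptional plasticity** (`chromoplast.plasticity`). Bulk RNA-seq
  counts → TPM → cleaning (ERCC/NaN removal, renormalization to 10⁶,
  zero-gene removal, replicate averaging) → |log₂FC| ≥ 1 gate → response as
  a function of baseline-expression decile, and Gaussian-KDE summaries of
  the log₂FC distribution of the lowest-baseline decile. Bimodality (up-
  *and* down-regulation, the CSC signature) is called with the sample
  bimodality coefficient against the uniform reference 5/9.
- **Intercellular heterogeneity** (`chromoplast.heterogeneity`). scRNA-seq
  QC (20 000–100 000 reads, < 15% mitochondrial, ≥ 200 features, genes in
  ≥ 3 cells), log-normalization (scale 10⁴), variable-gene scaling, PCA
  (dims 1–20), a pluggable 3D embedding, and the radius of genomic space
  per condition: *R*<sub>c</sub> = √(1/*N* Σᵢ ‖*r*ᵢ − *r̄*‖²).
- **Chromatin marks** (`chromoplast.marks`). CUT&Tag peak analytics:
  differential-peak gating, merged per-chromosome mark density
  (Σ bp<sub>mark</sub> / chromosome length, chrX excluded), cross-mark OLS
  regression (e.g. H3K27me3 vs H3K4me3 density), poised-gene calling
  (H3K4me3 ∧ H3K27me3 within ± 2 kb of the canonical TSS), peak feature
  annotation, and promoter log₂FC matrices with K-means (K = 6).

## Worked example

Simulate a two-group PWS cohort (30 nuclei per group, true nuclear packing
scaling 2.34 for ALDH+ vs 2.05 for ALDH−, sd 0.1, 5% spectral noise) and
recover the group difference:

```python
import numpy as np
from chromoplast import SimConfig, analyze_cube, compare_populations
from chromoplast.synthetic import gen_nucleus_cohort

cfg = SimConfig(seed=1)
cohort, truth = gen_nucleus_cohort(cfg)
calib = cfg.calibration()
dn = {g: np.array([analyze_cube(c, m, calib).d_n for c, m in nuclei])
      for g, nuclei in cohort.items()}
res = compare_populations(dn, control_label="ALDH-")
print({g: round(v, 3) for g, v in res.group_means.items()},
      f"p={res.p_values['ALDH+']:.2e}", res.significant["ALDH+"])
```

```
{'ALDH+': 2.339, 'ALDH-': 2.036} p=2.46e-20 True
```

The recovered means sit within a few thousandths of the planted values and
the Welch test is significant far below the 0.05/2 threshold — a higher
*D*<sub>n</sub> means more, denser chromatin packing domains in the
CSC-like group. The same generator-first pattern works for every other
stage (`gen_bulk_expression`, `gen_peaks` + `gen_annotation`,
`gen_single_cell`, `gen_embedding`).

A CLI mirrors the library for shell use:

```bash
chromoplast simulate bulk --seed 3 --out sim/
chromoplast plasticity --counts sim/counts.tsv --samples sim/samples.tsv --out plast/
chromoplast simulate peaks --seed 5 --out peaks/
chromoplast marks regress --bed peaks/H3K4me3.bed --bed peaks/H3K27me3.bed \
    --chrom-sizes peaks/chrom.sizes --out reg/
```

Every run writes a `manifest.json` with the configuration and seed.

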