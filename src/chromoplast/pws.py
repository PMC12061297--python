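"""Partial wave spectroscopic (PWS) microscopy image analysis.

A PWS acquisition is a 3D image cube I(lambda, x, y) of backscattered
intensity, captured here on a 515-685 nm grid at 2 nm steps (86 planes),
together with a reference cube from a cell-free region of the dish.  After
low-pass filtering along wavelength and normalization by the reference, the
per-pixel spectral standard deviation sigma(x, y) encodes nanoscale
chromatin density fluctuations.  A strictly monotone calibration maps sigma
to the local chromatin packing scaling D_a(x, y); averaging D_a over the
nuclear mask yields the nuclear packing scaling D_n.  Populations of nuclei
are compared with Welch's unequal-variance t-test at a Bonferroni-style
threshold of 0.05 / (number of groups).

The quantitative sigma <-> D mapping depends on optical parameters and the
chromatin density autocorrelation model of the instrument; it is exposed as
a pluggable :class:`CalibrationModel` rather than hard-coded physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

DEFAULT_WAVELENGTHS = np.arange(515.0, 685.0 + 1e-9, 2.0)  # nm, 86 planes


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectralCube:
    """Wavelength-resolved backscatter intensities plus cell-free reference."""

    intensities: np.ndarray  # (n_lambda, nx, ny), arbitrary units, >= 0
    wavelengths: np.ndarray  # nm, strictly increasing
    reference: np.ndarray    # same shape as intensities

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (n_lambda, nx, ny)")
        if self.wavelengths.shape != (self.intensities.shape[0],):
            raise ValueError("wavelength vector length must match cube planes")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.reference.shape != self.intensities.shape:
            raise ValueError("reference shape must match intensities")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")

    @property
    def n_wavelengths(self) -> int:
        return self.intensities.shape[0]


@dataclass
class CalibrationModel:
    """Strictly monotone sigma = f(D) mapping on an open D domain.

    families:
      - ``linear``: sigma = b * (D - 1), params = {"b": b}
      - ``power``:  sigma = a * (D - 1) ** c, params = {"a": a, "c": c}
    """

    family: str = "linear"
    params: dict = field(default_factory=lambda: {"b": 0.05})
    domain: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if self.family not in ("linear", "power"):
            raise ValueError(f"unknown calibration family {self.family!r}")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("empty calibration domain")
        grid = np.linspace(lo + 1e-6, hi - 1e-6, 257)
        fwd = self.forward(grid)
        if np.any(np.diff(fwd) <= 0):
            raise ValueError("calibration not strictly increasing on domain")
        if not np.allclose(self.inverse(fwd), grid, atol=1e-9):
            raise ValueError("calibration inverse round trip failed")

    def forward(self, d: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(d, dtype=float)
        if self.family == "linear":
            out = self.params["b"] * (d - 1.0)
        else:
            out = self.params["a"] * np.power(d - 1.0, self.params["c"])
        return out if out.ndim else float(out)

    def inverse(self, sigma: np.ndarray | float) -> np.ndarray | float:
        sigma = np.asarray(sigma, dtype=float)
        if self.family == "linear":
            out = 1.0 + sigma / self.params["b"]
        else:
            out = 1.0 + np.power(sigma / self.params["a"], 1.0 / self.params["c"])
        return out if out.ndim else float(out)

    def check_domain(self, d: np.ndarray) -> None:
        lo, hi = self.domain
        d = np.asarray(d, dtype=float)
        if np.any(d <= lo) or np.any(d >= hi):
            raise ValueError(
                f"D values outside invertible calibration domain ({lo}, {hi})"
            )


@dataclass
class NucleusImage:
    """Per-pixel D_a map with nuclear mask and scalar D_n."""

    d_map: np.ndarray
    mask: np.ndarray
    d_n: float
    clip_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.d_map.shape != self.mask.shape:
            raise ValueError("d_map / mask shape mismatch")
        if not np.all(np.isfinite(self.d_map[self.mask.astype(bool)])):
            raise ValueError("non-finite D_a inside mask")


@dataclass
class PopulationComparison:
    """Welch comparisons of per-nucleus D_n between groups and a control."""

    control_label: str
    labels: list[str]
    dn_values: dict[str, np.ndarray]
    group_means: dict[str, float]
    normalized_means: dict[str, float]
    t_statistics: dict[str, float]
    p_values: dict[str, float]
    alpha: float
    significant: dict[str, bool]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def butterworth_lowpass(
    cube: SpectralCube, order: int = 2, cutoff: float = 0.2
) -> SpectralCube:
    """Zero-phase Butterworth low-pass along the wavelength axis.

    Suppresses high-frequency LED illumination noise while preserving the
    slowly varying interference spectrum.  ``cutoff`` is in cycles/sample
    (Nyquist is 0.5); the filter is applied forward-backward (filtfilt) so
    the passband has zero phase shift and DC gain 1.
    """
    if not 0 < cutoff < 0.5:
        raise ValueError("cutoff must lie in (0, 0.5) cycles/sample")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = _signal.butter(order, cutoff * 2.0, btype="low", output="sos")
    padlen = 3 * (2 * len(sos) + 1)  # sosfiltfilt default edge padding
    if cube.n_wavelengths <= padlen:
        raise ValueError(
            f"cube has {cube.n_wavelengths} wavelength planes; the order-"
            f"{order} filter needs more than {padlen}"
        )
    filtered = _signal.sosfiltfilt(sos, cube.intensities, axis=0)
    return SpectralCube(
        np.clip(filtered, 0.0, None), cube.wavelengths, cube.reference
    )


def normalize_reference(cube: SpectralCube) -> np.ndarray:
    """Divide the cube by its cell-free reference, per pixel and wavelength."""
    bad = cube.reference <= 0
    if bad.any():
        idx = np.argwhere(bad)[:5]
        raise ValueError(
            f"reference has non-positive values at (plane, x, y) {idx.tolist()}"
        )
    return cube.intensities / cube.reference


def spectral_sigma(normalized: np.ndarray) -> np.ndarray:
    """Per-pixel sample standard deviation across wavelengths (ddof=1)."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape[0] < 2:
        raise ValueError("need at least 2 wavelength planes")
    if np.isnan(normalized).any():
        raise ValueError("NaN planes in normalized cube")
    return normalized.std(axis=0, ddof=1)


def sigma_to_d(
    sigma_map: np.ndarray, calib: CalibrationModel
) -> tuple[np.ndarray, dict]:
    """Invert the calibration per pixel; clip out-of-domain values to the edges.

    Returns (d_map, qc) where qc reports the fraction and counts of pixels
    clipped at either domain edge.  Clipping rather than dropping preserves
    pixel counts for nuclear averaging.
    """
    sigma_map = np.asarray(sigma_map, dtype=float)
    if np.any(sigma_map < 0):
        raise ValueError("negative sigma values")
    d = np.asarray(calib.inverse(sigma_map), dtype=float)
    lo, hi = calib.domain
    n_lo = int(np.sum(d < lo))
    n_hi = int(np.sum(d > hi))
    d = np.clip(d, lo, hi)
    qc = {
        "n_pixels": int(d.size),
        "n_clipped_low": n_lo,
        "n_clipped_high": n_hi,
        "clip_fraction": (n_lo + n_hi) / d.size,
    }
    return d, qc


def nuclear_dn(d_map: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of D_a over the nuclear mask."""
    mask = np.asarray(mask, dtype=bool)
    if d_map.shape != mask.shape:
        raise ValueError("d_map / mask shape mismatch")
    if not mask.any():
        raise ValueError("empty nuclear mask")
    return float(d_map[mask].mean())


def analyze_cube(
    cube: SpectralCube,
    mask: np.ndarray,
    calib: CalibrationModel,
    filter_order: int = 2,
    filter_cutoff: float = 0.2,
    apply_filter: bool = True,
) -> NucleusImage:
    """Full single-nucleus pipeline: filter -> normalize -> sigma -> D_a -> D_n."""
    if apply_filter:
        cube = butterworth_lowpass(cube, filter_order, filter_cutoff)
    normalized = normalize_reference(cube)
    sigma = spectral_sigma(normalized)
    d_map, qc = sigma_to_d(sigma, calib)
    d_n = nuclear_dn(d_map, mask)
    return NucleusImage(d_map, np.asarray(mask, dtype=bool), d_n, qc["clip_fraction"])


def otsu_mask(cube: SpectralCube) -> np.ndarray:
    """Fallback nucleus mask: Otsu threshold on the mean-intensity image."""
    mean_img = cube.intensities.mean(axis=0)
    lo, hi = mean_img.min(), mean_img.max()
    if hi == lo:
        raise ValueError("flat image; cannot derive a mask")
    # exhaustive Otsu over 256 candidate thresholds
    levels = np.linspace(lo, hi, 258)[1:-1]
    best_t, best_var = levels[0], -1.0
    flat = mean_img.ravel()
    for t in levels:
        fg = flat > t
        n1, n0 = fg.sum(), (~fg).sum()
        if n1 == 0 or n0 == 0:
            continue
        between = n1 * n0 * (flat[fg].mean() - flat[~fg].mean()) ** 2
        if between > best_var:
            best_var, best_t = between, t
    return mean_img > best_t


def compare_populations(
    groups: dict[str, np.ndarray], control_label: str
) -> PopulationComparison:
    """Welch t-test of each group's D_n against the control group.

    Means are also reported normalized to the control-group mean, and
    significance is called at alpha = 0.05 / N_groups.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < 3:
            raise ValueError(f"group {label!r} has fewer than 3 nuclei")
    control = arrays[control_label]
    control_mean = float(control.mean())
    alpha = 0.05 / len(arrays)
    means, norm_means, tstats, pvals, sig = {}, {}, {}, {}, {}
    for label, arr in arrays.items():
        means[label] = float(arr.mean())
        norm_means[label] = means[label] / control_mean
        if label == control_label:
            tstats[label], pvals[label], sig[label] = 0.0, 1.0, False
            continue
        t, p = _stats.ttest_ind(arr, control, equal_var=False)
        tstats[label], pvals[label] = float(t), float(p)
        sig[label] = bool(p < alpha)
    return PopulationComparison(
        control_label=control_label,
        labels=list(arrays),
        dn_values=arrays,
        group_means=means,
        normalized_means=norm_means,
        t_statistics=tstats,
        p_values=pvals,
        alpha=alpha,
        significant=sig,
    )
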