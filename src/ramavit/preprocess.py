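"""Spectral preprocessing and acquisition-quality screening.

The chain applied to a raw single-cell Raman spectrum before any statistic:

1. crop to the analysis window (default 600-3100 cm^-1, which retains the
   fingerprint region, the 1800-2040 cm^-1 silent region, the C-D band and
   the C-H band);
2. despike: cosmic-ray points more than ``despike_mad`` robust SDs above
   the local median are replaced by that median (window 5);
3. smooth: Savitzky-Golay polynomial moving fit;
4. baseline: modified-polynomial iterative fit — fit an order-k polynomial,
   clip the working spectrum to min(spectrum, fit), repeat — then subtract
   the final fit;
5. offset: subtract the median of the cell-silent region (1800-2040 cm^-1)
   so residual noise is centred on zero rather than on the lower noise
   envelope left by step 4;
6. normalise: divide by the summed intensity over ``norm_region`` so
   spectra share a common scale for classification (band *ratios* such as
   the C-D ratio are insensitive to this step).

Quality screening keeps cells whose signal-to-noise ratio — peak intensity
in the C-H band (2800-3100 cm^-1) over the noise SD in the silent region —
reaches ``snr_min``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .errors import RamavitError
from .spectra import Band, Ramanome, Spectrum

__all__ = [
    "PreprocessConfig",
    "QualityReport",
    "preprocess_spectrum",
    "preprocess_ramanome",
    "compute_snr",
    "quality_screen",
    "CH_BAND",
    "SILENT_BAND",
]

CH_BAND = Band("C-H", 2800.0, 3100.0)
SILENT_BAND = Band("silent", 1800.0, 2040.0)


@dataclass(frozen=True)
class PreprocessConfig:
    crop_lo: float = 600.0
    crop_hi: float = 3100.0
    smooth_window: int = 11
    smooth_order: int = 3
    baseline_order: int = 4
    baseline_iters: int = 50
    despike_window: int = 5
    despike_mad: float = 6.0
    norm_region: Band = field(default_factory=lambda: Band("norm", 600.0, 3100.0))
    offset_region: Band = field(default_factory=lambda: SILENT_BAND)
    normalize: bool = True
    snr_min: float = 5.0

    def __post_init__(self):
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_order:
            raise RamavitError("smooth_window must be odd and > smooth_order")
        if self.baseline_iters < 1:
            raise RamavitError("baseline_iters must be >= 1")
        if self.crop_lo >= self.crop_hi:
            raise RamavitError("crop_lo must be < crop_hi")


@dataclass(frozen=True)
class QualityReport:
    cell_id: str
    snr: float
    passed: bool


def _despike(y: np.ndarray, window: int, n_mad: float) -> np.ndarray:
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad == 0:
        return y
    out = y.copy()
    spikes = resid > n_mad * 1.4826 * mad
    out[spikes] = med[spikes]
    return out


def _modpoly_baseline(x: np.ndarray, y: np.ndarray, order: int, iters: int) -> np.ndarray:
    """Iterative clipped polynomial fit, refined on non-peak points.

    The clipping iterations (fit, clip the working spectrum to
    min(spectrum, fit), repeat) find an approximate lower envelope; a
    final pass refits the polynomial by ordinary least squares on the
    points that are not peaks (residual below 3 robust SD), so that over
    background regions the baseline runs through the middle of the noise
    rather than along its lower edge.
    """
    # scale x to [-1, 1] for numerical conditioning of the Vandermonde fit
    xs = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(xs, order)
    # precompute the least-squares projector once; y changes each iteration
    pinv = np.linalg.pinv(V)
    work = y.copy()
    fit = work
    for _ in range(iters):
        fit = V @ (pinv @ work)
        work = np.minimum(work, fit)
    for _ in range(3):
        resid = y - fit
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        keep = resid <= 3.0 * sigma + 1e-12 * max(1.0, float(np.abs(y).max()))
        if keep.sum() <= order + 1:
            break
        coef, *_ = np.linalg.lstsq(V[keep], y[keep], rcond=None)
        fit = V @ coef
    return fit


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Apply the full crop/despike/smooth/baseline/offset/normalise chain."""
    cfg = cfg or PreprocessConfig()
    if cfg.crop_lo < s.wavenumbers[0] or cfg.crop_hi > s.wavenumbers[-1]:
        raise RamavitError(
            f"crop window [{cfg.crop_lo}, {cfg.crop_hi}] outside spectral axis "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    out = s.crop(cfg.crop_lo, cfg.crop_hi)
    y = _despike(out.intensities, cfg.despike_window, cfg.despike_mad)
    if y.size > cfg.smooth_window:
        y = savgol_filter(y, cfg.smooth_window, cfg.smooth_order)
    base = _modpoly_baseline(out.wavenumbers, y, cfg.baseline_order, cfg.baseline_iters)
    y = y - base
    off = cfg.offset_region.mask(out.wavenumbers)
    if off.any():
        y = y - np.median(y[off])
    if cfg.normalize:
        nm = cfg.norm_region.mask(out.wavenumbers)
        total = float(np.sum(np.clip(y[nm], 0.0, None)))
        if total > 0:
            y = y / total
    return Spectrum(out.wavenumbers, y, s.meta)


def preprocess_ramanome(r: Ramanome, cfg: PreprocessConfig | None = None) -> Ramanome:
    spectra = [preprocess_spectrum(s, cfg) for s in r]
    axis = spectra[0].wavenumbers if spectra else None
    common = (
        axis is not None
        and all(np.array_equal(s.wavenumbers, axis) for s in spectra)
    )
    return Ramanome(spectra, axis=axis if common else None)


def compute_snr(s: Spectrum) -> float:
    """Peak C-H intensity over silent-region noise SD (0/0 -> 0)."""
    w = s.wavenumbers
    sig = CH_BAND.mask(w)
    quiet = SILENT_BAND.mask(w)
    if not sig.any() or not quiet.any():
        raise RamavitError(
            "spectrum must cover both the C-H (2800-3100) and silent "
            "(1800-2040) regions to compute SNR"
        )
    peak = float(np.max(np.clip(s.intensities[sig], 0.0, None)))
    noise = float(np.std(s.intensities[quiet]))
    if noise == 0.0:
        return 0.0 if peak == 0.0 else math.inf
    return peak / noise


def quality_screen(
    r: Ramanome, cfg: PreprocessConfig | None = None
) -> tuple[Ramanome, list[QualityReport]]:
    """Partition a preprocessed ramanome by the SNR threshold.

    Returns the passing subset plus a report for every input cell.
    """
    cfg = cfg or PreprocessConfig()
    reports: list[QualityReport] = []
    kept: list[Spectrum] = []
    for s in r:
        snr = compute_snr(s)
        ok = snr >= cfg.snr_min
        reports.append(QualityReport(cell_id=s.meta.cell_id, snr=snr, passed=ok))
        if ok:
            kept.append(s)
    axis = r.axis if r.axis is not None else None
    return Ramanome(kept, axis=axis), reports
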