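"""Chemometric preprocessing for seed reflectance spectra.

The default pipeline is Savitzky-Golay smoothing (window 11, order 2)
followed by clipping to [0, 1]; polynomial baseline correction and SNV are
available but off by default.  Bandwise standardization (zero mean, unit
variance per wavelength, sample-variance denominator N-1) prepares the matrix
for PCA and distance-based modelling and is always fitted on training rows
only when used for supervised work.

Edge handling for the smoother: each of the first/last ``window//2`` points
is the value at its own position of a least-squares polynomial fitted to the
truncated window of available samples (no padding), so polynomial inputs of
degree <= the filter order pass through unchanged at every point, edges
included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs

from .calibration import SpectralDataset, WavelengthGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the preprocessing pipeline.

    SNV output is a centred, variance-normalised space that is not directly
    interpretable as reflectance, so the [0, 1] clip is skipped when SNV is
    enabled.
    """

    sg_window: int = 11
    sg_order: int = 2
    baseline_degree: int = 2
    apply_baseline: bool = False
    apply_snv: bool = False
    clip_low: float = 0.0
    clip_high: float = 1.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if not self.clip_low < self.clip_high:
            raise ValueError("clip_low must be below clip_high")


@dataclass
class BandScaler:
    """Per-band standardization parameters: mu_j (mean, 1/N) and sigma_j (sd, 1/(N-1))."""

    mu: np.ndarray
    sigma: np.ndarray
    zero_variance_bands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


# ---------------------------------------------------------------------------
# Single-spectrum operations (all accept a vector or an N x P matrix)
# ---------------------------------------------------------------------------

def savgol_smooth(spectrum: np.ndarray, window: int = 11, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing with truncated-window least-squares edges."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= order:
        raise ValueError(f"window ({window}) must exceed polynomial order ({order})")
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    p = x.shape[1]
    if p < window:
        raise ValueError(f"spectrum length {p} shorter than window {window}")

    half = window // 2
    coeffs = savgol_coeffs(window, order)[::-1]
    out = np.empty_like(x)
    # interior: standard centered convolution (symmetric smoothing weights)
    windows = np.lib.stride_tricks.sliding_window_view(x, window, axis=1)
    out[:, half:p - half] = windows @ coeffs
    # edges: least-squares polynomial on the truncated available window
    for i in range(half):
        for idx, lo, hi in ((i, 0, i + half + 1), (p - 1 - i, p - half - 1 - i, p)):
            t = np.arange(lo, hi) - idx
            design = np.vander(t, order + 1, increasing=True)
            # projection row picking the fitted value at t = 0
            proj = np.linalg.pinv(design)[0]
            out[:, idx] = x[:, lo:hi] @ proj
    return out[0] if squeeze else out


def snv_transform(spectrum: np.ndarray, seed_id: str | None = None) -> np.ndarray:
    """Standard normal variate: centre each spectrum and scale to unit sample sd.

    Uses the sample-sd convention (P-1 denominator).  Constant spectra are
    rejected because sigma_i = 0.
    """
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    sd = x.std(axis=1, ddof=1)
    bad = sd == 0
    if bad.any():
        which = seed_id if seed_id is not None else f"row(s) {np.flatnonzero(bad).tolist()}"
        raise ValueError(f"SNV undefined for constant spectrum: {which}")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if squeeze else out


def baseline_correct(spectrum: np.ndarray, grid: WavelengthGrid, degree: int = 2) -> np.ndarray:
    """Subtract the full-spectrum least-squares polynomial baseline of given degree."""
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if degree >= x.shape[1]:
        raise ValueError(f"degree ({degree}) must be below the number of bands ({x.shape[1]})")
    lam = grid.values
    # center/scale the axis for conditioning
    t = (lam - lam.mean()) / (lam.std() if lam.std() else 1.0)
    design = np.vander(t, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    out = x - (design @ coef).T
    return out[0] if squeeze else out


def clip01(spectrum: np.ndarray, low: float = 0.0, high: float = 1.0) -> np.ndarray:
    """Clip reflectance to a physically plausible interval (default [0, 1])."""
    return np.clip(np.asarray(spectrum, dtype=float), low, high)


# ---------------------------------------------------------------------------
# Bandwise standardization
# ---------------------------------------------------------------------------

def fit_band_scaler(X_train: np.ndarray) -> BandScaler:
    """Fit per-band mean (1/N) and sample sd (1/(N-1)) on training rows only."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("band scaler requires a 2-D matrix with at least 2 rows")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sigma == 0)
    if zero.size:
        logger.warning("band scaler: %d zero-variance band(s): %s", zero.size, zero.tolist())
    return BandScaler(mu=mu, sigma=sigma, zero_variance_bands=zero)


def apply_band_scaler(scaler: BandScaler, X: np.ndarray) -> np.ndarray:
    """Standardize columns; zero-variance bands map to 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != scaler.mu.shape[0]:
        raise ValueError(f"band count mismatch: X has {X.shape[-1]}, scaler has {scaler.mu.shape[0]}")
    safe = np.where(scaler.sigma == 0, 1.0, scaler.sigma)
    out = (X - scaler.mu) / safe
    if scaler.zero_variance_bands.size:
        out[..., scaler.zero_variance_bands] = 0.0
    return out


# ---------------------------------------------------------------------------
# Dataset-level pipeline
# ---------------------------------------------------------------------------

def preprocess_dataset(dataset: SpectralDataset,
                       config: PreprocessConfig | None = None) -> SpectralDataset:
    """Apply the configured pipeline to every spectrum of a dataset.

    Fixed stage order: Savitzky-Golay smoothing, then (optionally) baseline
    correction and SNV, then clipping to [0, 1] -- except that clipping is
    skipped when SNV is enabled, since SNV output is not reflectance.
    """
    cfg = config or PreprocessConfig()
    X = savgol_smooth(dataset.X, cfg.sg_window, cfg.sg_order)
    steps = [f"savgol(window={cfg.sg_window}, order={cfg.sg_order})"]
    if cfg.apply_baseline:
        X = baseline_correct(X, dataset.grid, cfg.baseline_degree)
        steps.append(f"baseline(degree={cfg.baseline_degree})")
    if cfg.apply_snv:
        X = snv_transform(X)
        steps.append("snv(sample-sd)")
    else:
        X = clip01(X, cfg.clip_low, cfg.clip_high)
        steps.append(f"clip[{cfg.clip_low}, {cfg.clip_high}]")
    logger.info("preprocess pipeline: %s", " -> ".join(steps))
    return SpectralDataset(X=X, grid=dataset.grid, labels=dataset.labels,
                           seed_ids=dataset.seed_ids)
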