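"""PCA on the bandwise-standardized spectral matrix.

Scores, loadings, explained-variance ratios (sample covariance, 1/(N-1)),
accession centroids in score space, and cumulative variance.  Component signs
follow a deterministic rule: each loading vector is flipped so that its
largest-magnitude entry is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .preprocess import BandScaler, apply_band_scaler, fit_band_scaler

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    scaler: BandScaler
    loadings: np.ndarray                 # P x K, orthonormal columns
    explained_variance_ratio: np.ndarray  # length K, non-increasing
    n_components: int
    scores: np.ndarray                   # N x K scores of the fit data
    mean_: np.ndarray                    # column means of the standardized fit matrix


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    flips = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flips[flips == 0] = 1.0
    return flips


def fit_pca(X: np.ndarray, n_components: int = 20,
            standardize: bool = True) -> PCAModel:
    """Fit PCA, by default on the bandwise-standardized matrix.

    ``standardize=False`` runs PCA on the raw matrix (sensitivity use only);
    the internal scaler is then an identity transform.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 rows")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}], got {n_components}")

    if standardize:
        scaler = fit_band_scaler(X)
    else:
        scaler = BandScaler(mu=np.zeros(p), sigma=np.ones(p))
    Xs = apply_band_scaler(scaler, X)

    sk = _SkPCA(n_components=n_components, svd_solver="full")
    scores = sk.fit_transform(Xs)
    loadings = sk.components_.T
    flips = _fix_signs(loadings)
    return PCAModel(scaler=scaler, loadings=loadings * flips,
                    explained_variance_ratio=sk.explained_variance_ratio_.copy(),
                    n_components=n_components, scores=scores * flips,
                    mean_=sk.mean_.copy())


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project new spectra into the fitted score space."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.loadings.shape[0]:
        raise ValueError(f"band count mismatch: X has {X.shape[-1]} bands, "
                         f"model expects {model.loadings.shape[0]}")
    Xs = apply_band_scaler(model.scaler, X)
    return (Xs - model.mean_) @ model.loadings


def accession_centroids(scores: np.ndarray, labels) -> tuple[list, np.ndarray]:
    """Per-accession mean score vectors; labels returned in sorted order."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    centroids = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    return [str(c) for c in classes], centroids


def cumulative_variance(ratios: np.ndarray, k: int) -> float:
    """Cumulative explained-variance fraction of the first k components."""
    ratios = np.asarray(ratios, dtype=float)
    if not 1 <= k <= len(ratios):
        raise ValueError(f"k must be in [1, {len(ratios)}], got {k}")
    return float(ratios[:k].sum())
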