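"""ReliefF wavelength ranking for multiclass spectral data.

For each reference spectrum i (all training rows, in deterministic order),
ReliefF finds its k nearest *hits* (same accession, excluding i itself) and
k nearest *misses* (nearest rows of any other accession, pooled) by Euclidean
distance in the full band space, then updates every band weight

    w_j <- w_j - (1/(m k)) sum_{h in H_i} |x_ij - x_hj|
               + (1/(m k)) sum_{r in M_i} |x_ij - x_rj|

with m the number of reference spectra.  Raw absolute differences are used
(no max-min range normalization): reflectance is already in [0, 1].

Deterministic conventions: neighbor distance ties break by ascending row
index; weight ties in the ranking break by ascending wavelength.  With m set
to all training rows the pass is fully deterministic and the RNG seed only
matters when a reference subsample is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import WavelengthGrid

logger = logging.getLogger(__name__)


@dataclass
class ReliefFResult:
    weights: np.ndarray       # length P
    ranking: np.ndarray       # band indices, descending weight
    top_k: np.ndarray         # first K of the ranking (default K = 16)
    params: dict
    train_row_ids: np.ndarray | None = None


def relieff_weights(
    X_train: np.ndarray,
    y_train,
    k: int = 20,
    seed: int = 42,
    n_reference: int | None = None,
    default_top_k: int = 16,
    row_roles=None,
    train_row_ids=None,
) -> ReliefFResult:
    """Compute ReliefF band weights on the training partition.

    Parameters
    ----------
    k
        Number of nearest hits and nearest misses per reference spectrum.
    n_reference
        Reference spectra m; ``None`` uses all training rows (deterministic).
        A smaller value subsamples references without replacement (seeded).
    row_roles
        Optional per-row provenance tags; any value other than ``"train"``
        rejects the call (leakage guard: ranking must never see test rows).
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    n, p = X.shape
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if row_roles is not None:
        roles = np.asarray(row_roles)
        if np.any(roles != "train"):
            bad = np.unique(roles[roles != "train"]).tolist()
            raise ValueError(f"ReliefF must be computed on the training partition only; "
                             f"found rows tagged {bad}")

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least 2 classes")
    too_small = counts < k + 1
    if too_small.any():
        c = classes[too_small][0]
        raise ValueError(f"class {c!r} has {counts[too_small][0]} members; "
                         f"need >= k+1 = {k + 1} for hit retrieval")

    rng = np.random.default_rng(seed)
    if n_reference is None or n_reference >= n:
        refs = np.arange(n)
    else:
        refs = np.sort(rng.choice(n, size=n_reference, replace=False))
    m = len(refs)

    # full pairwise squared distances (ties in d^2 == ties in d)
    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    idx_all = np.arange(n)
    weights = np.zeros(p)
    for i in refs:
        same = y == y[i]
        hit_pool = idx_all[same & (idx_all != i)]
        miss_pool = idx_all[~same]
        # stable sort over ascending-index pools => distance ties break by row index
        hits = hit_pool[np.argsort(d2[i, hit_pool], kind="stable")[:k]]
        misses = miss_pool[np.argsort(d2[i, miss_pool], kind="stable")[:k]]
        weights += np.abs(X[i] - X[misses]).sum(axis=0)
        weights -= np.abs(X[i] - X[hits]).sum(axis=0)
    weights /= m * k

    ranking = np.argsort(-weights, kind="stable")  # weight desc, wavelength asc on ties
    result = ReliefFResult(
        weights=weights,
        ranking=ranking,
        top_k=ranking[:default_top_k].copy(),
        params={"k_neighbors": k, "n_reference": m, "seed": seed},
        train_row_ids=None if train_row_ids is None else np.asarray(train_row_ids),
    )
    logger.info("ReliefF: m=%d references, k=%d, P=%d; top band index %d",
                m, k, p, int(ranking[0]))
    return result


def top_k_bands(result: ReliefFResult, K: int = 16,
                grid: WavelengthGrid | None = None) -> pd.DataFrame:
    """The K highest-weight bands, sorted by wavelength, with weights attached.

    Weight ties break by ascending wavelength (already encoded in the stored
    ranking).
    """
    p = len(result.weights)
    if not 1 <= K <= p:
        raise ValueError(f"K must be in [1, {p}], got {K}")
    selected = np.sort(result.ranking[:K])
    wavelengths = grid.values[selected] if grid is not None else selected.astype(float)
    return pd.DataFrame({
        "band_index": selected,
        "wavelength_nm": wavelengths,
        "weight": result.weights[selected],
    })
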