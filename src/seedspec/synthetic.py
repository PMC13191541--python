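"""Synthetic VNIR seed spectra and hypercubes with known ground truth.

Real seed reflectance in the 423-1022 nm range shows strong visible
absorption, a sigmoid rise near the red edge (~700 nm), and a smooth, higher
near-infrared plateau.  Each accession archetype is modelled as::

    R(lambda) = base_albedo + nir_amplitude * sigmoid((lambda - c) / w)
                - sum_f depth_f * exp(-(lambda - center_f)^2 / (2 width_f^2))

Individual seeds deviate from their accession archetype through a per-seed
multiplicative gain (scattering/albedo variation), a per-seed additive
offset, smooth low-frequency noise (correlated across wavelength), and iid
per-band sensor noise; the result is clipped to [0, 1].

Two difficulty presets control class geometry:

* ``easy`` -- every pair of archetypes is well separated (max absolute curve
  difference > 0.05), via a lattice of visible/NIR reflectance levels.
* ``hard`` -- three designated accession pairs are near-duplicates (max curve
  difference < 0.02, a single faint extra absorption dip), inducing
  structured, reciprocal confusions downstream.

When a *planted window* is given, all accessions share one base curve and
differ only in the depth of an absorption feature centred inside the window,
so the window carries all of the class signal -- the ground truth for band
ranking recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .calibration import HyperCube, ROISpec, SpectralDataset, WavelengthGrid

logger = logging.getLogger(__name__)

CURVE_LOW, CURVE_HIGH = 0.02, 0.98
BACKGROUND_REFLECTANCE = 0.05


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of one accession's mean reflectance curve."""

    accession_id: str
    base_albedo: float
    nir_amplitude: float
    transition_center_nm: float = 700.0
    transition_width_nm: float = 20.0
    absorption_features: tuple = ()  # (center_nm, depth, width_nm) triples

    def __post_init__(self) -> None:
        if self.transition_width_nm <= 0:
            raise ValueError("transition_width_nm must be positive")
        for _, depth, width in self.absorption_features:
            if depth < 0 or width <= 0:
                raise ValueError("absorption feature depths must be >= 0 and widths > 0")

    def curve(self, grid: WavelengthGrid) -> np.ndarray:
        """Evaluate the archetype on the grid, bounded to [0.02, 0.98]."""
        lam = grid.values
        r = self.base_albedo + self.nir_amplitude / (
            1.0 + np.exp(-(lam - self.transition_center_nm) / self.transition_width_nm))
        for center, depth, width in self.absorption_features:
            r = r - depth * np.exp(-0.5 * ((lam - center) / width) ** 2)
        return np.clip(r, CURVE_LOW, CURVE_HIGH)


@dataclass(frozen=True)
class NoiseModel:
    """Per-seed and per-band noise magnitudes (reflectance units unless noted)."""

    mult_sd: float = 0.03       # per-seed gain spread (unitless, gain ~ N(1, mult_sd))
    add_sd: float = 0.01        # per-seed offset spread
    smooth_sd: float = 0.008    # low-frequency (wavelength-correlated) noise amplitude
    smooth_corr_nm: float = 50.0  # correlation length of the smooth noise
    sensor_sd: float = 0.003    # iid per-band sensor noise
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.mult_sd, self.add_sd, self.smooth_sd, self.sensor_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.smooth_corr_nm <= 0:
            raise ValueError("smooth_corr_nm must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to regenerate a dataset and verify recovery against it."""

    archetypes: tuple
    planted_window_nm: tuple | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    difficulty_preset: str = "easy"
    near_duplicate_pairs: tuple = ()  # ((label_a, label_b), ...) designed confusions

    @property
    def labels(self) -> list:
        return [a.accession_id for a in self.archetypes]


# ---------------------------------------------------------------------------
# Archetype construction
# ---------------------------------------------------------------------------

def _lattice_levels(n: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Visible/NIR reflectance level lattice guaranteeing pairwise separation.

    Adjacent visible levels differ by 0.06 and NIR plateau levels by 0.13, so
    any two accessions differ by > 0.05 somewhere on the curve.
    """
    n_vis = min(8, n)
    n_nir = -(-n // n_vis)  # ceil
    if n_nir > 4:
        raise ValueError(f"lattice supports at most 32 accessions, got {n}")
    vis = 0.06 + 0.06 * np.arange(n_vis)
    nir = np.array([0.55, 0.68, 0.81, 0.94])[:n_nir]
    return vis, nir, n_vis


def build_archetypes(
    n_accessions: int,
    grid: WavelengthGrid,
    preset: str = "easy",
    planted_window_nm: tuple | None = None,
    seed: int = 42,
) -> SyntheticTruth:
    """Construct accession archetypes for the requested difficulty preset.

    With ``planted_window_nm`` set, accessions share a single base curve and
    receive distinct absorption depths centred inside the window (all class
    signal inside the window).  Otherwise the ``easy`` preset places
    accessions on a well-separated reflectance lattice, and ``hard``
    additionally collapses three accession pairs into near-duplicates.
    """
    if n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    if preset not in ("easy", "hard"):
        raise ValueError(f"unknown preset {preset!r}; expected 'easy' or 'hard'")
    rng = np.random.default_rng(seed)
    ids = [f"A{i + 1:02d}" for i in range(n_accessions)]

    if planted_window_nm is not None:
        low, high = planted_window_nm
        if not (grid.start_nm <= low < high <= grid.end_nm):
            raise ValueError(
                f"planted window ({low}, {high}) nm lies outside the grid range "
                f"[{grid.start_nm}, {grid.end_nm}] nm")
        center = 0.5 * (low + high)
        depths = np.linspace(0.06, 0.50, n_accessions)
        archetypes = tuple(
            ArchetypeParams(
                accession_id=ids[i],
                base_albedo=0.55,
                nir_amplitude=0.30,
                transition_width_nm=20.0,
                absorption_features=((center, float(depths[i]), 4.0),),
            )
            for i in range(n_accessions)
        )
        return SyntheticTruth(archetypes=archetypes,
                              planted_window_nm=(float(low), float(high)),
                              noise=NoiseModel(seed=seed),
                              difficulty_preset=preset)

    vis, nir, n_vis = _lattice_levels(n_accessions)
    archetypes = []
    for i in range(n_accessions):
        v = float(vis[i % n_vis])
        plateau = float(nir[i // n_vis])
        n_dips = int(rng.integers(1, 4))
        dips = tuple(
            (float(rng.uniform(480.0, 660.0)), float(rng.uniform(0.005, 0.03)),
             float(rng.uniform(8.0, 15.0)))
            for _ in range(n_dips)
        )
        archetypes.append(ArchetypeParams(
            accession_id=ids[i],
            base_albedo=v,
            nir_amplitude=plateau - v,
            transition_width_nm=float(rng.uniform(15.0, 25.0)),
            absorption_features=dips,
        ))

    pairs: tuple = ()
    if preset == "hard":
        # Near-duplicate pairs: the second member copies the first and adds a
        # single faint dip (max curve difference 0.003 << 0.02), so the two
        # accessions are separable only marginally relative to seed noise.
        designed = [(0, 1), (2, 3), (4, 5)][: max(2, min(3, n_accessions // 2))]
        pair_labels = []
        for p, (a, b) in enumerate(designed):
            if b >= n_accessions:
                break
            twin = archetypes[a]
            extra = ((620.0 + 25.0 * p, 0.003, 8.0),)
            archetypes[b] = ArchetypeParams(
                accession_id=ids[b],
                base_albedo=twin.base_albedo,
                nir_amplitude=twin.nir_amplitude,
                transition_center_nm=twin.transition_center_nm,
                transition_width_nm=twin.transition_width_nm,
                absorption_features=twin.absorption_features + extra,
            )
            pair_labels.append((ids[a], ids[b]))
        pairs = tuple(pair_labels)

    return SyntheticTruth(archetypes=tuple(archetypes), planted_window_nm=None,
                          noise=NoiseModel(seed=seed), difficulty_preset=preset,
                          near_duplicate_pairs=pairs)


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, n: int, p: int, sd: float,
                  corr_bands: float) -> np.ndarray:
    """Wavelength-correlated Gaussian noise with marginal sd ``sd`` per band."""
    if sd == 0:
        return np.zeros((n, p))
    white = rng.standard_normal((n, p))
    smooth = gaussian_filter1d(white, corr_bands, axis=1, mode="reflect")
    # normalize by the filter's interior gain so the marginal sd is `sd`
    impulse = np.zeros(p)
    impulse[p // 2] = 1.0
    gain = np.sqrt(np.sum(gaussian_filter1d(impulse, corr_bands, mode="reflect") ** 2))
    return sd * smooth / gain


def simulate_dataset(truth: SyntheticTruth, n_seeds_per_accession: int,
                     grid: WavelengthGrid) -> SpectralDataset:
    """Simulate a balanced seed-level spectra table from the ground truth.

    Each row is ``gain * archetype + offset + smooth noise + sensor noise``,
    clipped to [0, 1].  Generation is deterministic given the truth's RNG
    seed: identical inputs give bit-identical datasets.
    """
    if n_seeds_per_accession < 1:
        raise ValueError("n_seeds_per_accession must be >= 1")
    nm = truth.noise
    rng = np.random.default_rng(nm.seed)
    corr_bands = nm.smooth_corr_nm / grid.spacing_nm

    rows, labels, seed_ids = [], [], []
    for arche in truth.archetypes:
        curve = arche.curve(grid)
        k = n_seeds_per_accession
        gains = 1.0 + nm.mult_sd * rng.standard_normal(k)
        offsets = nm.add_sd * rng.standard_normal(k)
        smooth = _smooth_noise(rng, k, grid.n_bands, nm.smooth_sd, corr_bands)
        sensor = nm.sensor_sd * rng.standard_normal((k, grid.n_bands)) if nm.sensor_sd else 0.0
        block = gains[:, None] * curve[None, :] + offsets[:, None] + smooth + sensor
        rows.append(np.clip(block, 0.0, 1.0))
        labels.extend([arche.accession_id] * k)
        seed_ids.extend(f"{arche.accession_id}_s{j + 1:03d}" for j in range(k))

    dataset = SpectralDataset(X=np.vstack(rows), grid=grid,
                              labels=np.array(labels), seed_ids=np.array(seed_ids))
    logger.info("simulated dataset: %d accessions x %d seeds = %d spectra, P=%d",
                len(truth.archetypes), n_seeds_per_accession, dataset.n, dataset.p)
    return dataset


# ---------------------------------------------------------------------------
# Hypercube simulation
# ---------------------------------------------------------------------------

_CELL = 20          # pixels per seed cell
_DISK_DIAMETER = 15  # seed disk diameter in pixels (>= 14 per contract)


def simulate_hypercube(
    truth: SyntheticTruth,
    seeds_per_dish: int,
    grid: WavelengthGrid,
    dn_dark: float = 100.0,
    dn_white: float = 4000.0,
    frame_shape: tuple | None = None,
) -> tuple[HyperCube, list[ROISpec], list[str]]:
    """Render seeds as reflectance disks in a dish and encode as raw DN.

    ``DN = dark + R * (white - dark) + sensor noise`` with per-band constant
    dark/white reference vectors.  Seeds are disks (diameter 15 px) on a
    background of reflectance 0.05; each returned ROI is a 10x10 square fully
    inside its disk.  Returns the cube, the ROI specs, and the true accession
    label of each ROI (seeds assigned to accessions cyclically).
    """
    if not dn_white > dn_dark >= 0:
        raise ValueError("require dn_white > dn_dark >= 0")
    if seeds_per_dish < 1:
        raise ValueError("seeds_per_dish must be >= 1")

    n_cols = int(np.ceil(np.sqrt(seeds_per_dish)))
    n_rows = int(np.ceil(seeds_per_dish / n_cols))
    needed = (n_rows * _CELL, n_cols * _CELL)
    if frame_shape is None:
        frame_shape = needed
    elif frame_shape[0] < needed[0] or frame_shape[1] < needed[1]:
        raise ValueError(
            f"layout overflow: {seeds_per_dish} seeds need a frame of at least "
            f"{needed[0]}x{needed[1]} px, got {frame_shape[0]}x{frame_shape[1]}")

    nm = truth.noise
    rng = np.random.default_rng(nm.seed)
    corr_bands = nm.smooth_corr_nm / grid.spacing_nm
    p = grid.n_bands
    refl = np.full((*frame_shape, p), BACKGROUND_REFLECTANCE, dtype=float)

    rois: list[ROISpec] = []
    roi_labels: list[str] = []
    yy, xx = np.mgrid[0:frame_shape[0], 0:frame_shape[1]]
    radius = _DISK_DIAMETER / 2.0
    for s in range(seeds_per_dish):
        arche = truth.archetypes[s % len(truth.archetypes)]
        curve = arche.curve(grid)
        gain = 1.0 + nm.mult_sd * rng.standard_normal()
        offset = nm.add_sd * rng.standard_normal()
        smooth = _smooth_noise(rng, 1, p, nm.smooth_sd, corr_bands)[0]
        spectrum = np.clip(gain * curve + offset + smooth, 0.0, 1.0)

        cy = (s // n_cols) * _CELL + _CELL // 2
        cx = (s % n_cols) * _CELL + _CELL // 2
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        refl[mask] = spectrum
        sid = f"seed{s + 1:03d}"
        rois.append(ROISpec(seed_id=sid, top_row=cy - 5, left_col=cx - 5))
        roi_labels.append(arche.accession_id)

    dark = np.full(p, float(dn_dark))
    white = np.full(p, float(dn_white))
    dn = dark + refl * (white - dark)
    if nm.sensor_sd:
        dn = dn + nm.sensor_sd * (dn_white - dn_dark) * rng.standard_normal(dn.shape)
    cube = HyperCube(dn=dn, dark=dark, white=white, grid=grid)
    logger.info("simulated hypercube: %d seeds, frame %dx%d, P=%d",
                seeds_per_dish, frame_shape[0], frame_shape[1], p)
    return cube, rois, roi_labels
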