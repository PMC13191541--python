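"""Reduced-band sensitivity study and full-pipeline orchestration.

A deployable multispectral sensor carries far fewer bands than a lab
hyperspectral camera.  Three reduction schemes are compared against the
full-spectrum baseline under the same fixed stratified 80/20 hold-out split:

* ``topk``       -- only the top K = 16 wavelengths ranked by ReliefF
                    (ranking computed on the training partition only);
* ``window``     -- only the green interval 562.85-584.65 nm (bounds
                    inclusive);
* ``downsample`` -- uniform wavelength grids at 5-30 nm steps, each target
                    mapped to the nearest measured band.

``run_full_pipeline`` chains every stage -- simulate, preprocess,
exploratory statistics, PCA, ReliefF, classification, reduced-band study --
into one reproducible run directory with a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import SpectralDataset, WavelengthGrid, write_dataset_csv
from .evaluation import (SplitSpec, cluster_bootstrap_ci, evaluate,
                         exact_binomial_ci, fit_baseline_classifier,
                         majority_vote_accuracy, stratified_holdout_split)
from .exploratory import (accession_means, euclidean_distance_matrix,
                          hierarchical_cluster, max_association,
                          ovr_association_map, permanova)
from .pca import cumulative_variance, fit_pca
from .preprocess import (PreprocessConfig, apply_band_scaler, fit_band_scaler,
                         preprocess_dataset)
from .relieff import relieff_weights, top_k_bands
from .synthetic import build_archetypes, simulate_dataset

logger = logging.getLogger(__name__)

GREEN_WINDOW_NM = (562.85, 584.65)
DEFAULT_DOWNSAMPLE_STEPS_NM = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
PIPELINE_STAGES = ("simulate", "preprocess", "exploratory", "pca", "relieff",
                   "classify", "reduced_band")


# ---------------------------------------------------------------------------
# Band selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSelection:
    mode: str                 # topk | window | downsample | full
    band_indices: np.ndarray  # strictly increasing, inside the grid
    wavelengths: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_bands(self) -> int:
        return len(self.band_indices)


def select_window(grid: WavelengthGrid, low_nm: float = GREEN_WINDOW_NM[0],
                  high_nm: float = GREEN_WINDOW_NM[1]) -> BandSelection:
    """All bands whose wavelength lies in the closed interval [low, high] nm."""
    if not low_nm < high_nm:
        raise ValueError("window bounds must satisfy low < high")
    # bounds are typically quoted to 2 decimals; allow half-print slack so a
    # band whose wavelength prints as the bound is included
    tol = 0.005
    mask = (grid.values >= low_nm - tol) & (grid.values <= high_nm + tol)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"window ({low_nm}, {high_nm}) nm contains no grid bands")
    return BandSelection(mode="window", band_indices=idx,
                         wavelengths=grid.values[idx],
                         params={"low_nm": low_nm, "high_nm": high_nm})


def uniform_downsample(grid: WavelengthGrid, step_nm: float) -> BandSelection:
    """Nearest-band mapping of a uniform wavelength grid spanning the full range."""
    if step_nm < grid.spacing_nm:
        raise ValueError(f"step ({step_nm} nm) must be >= native spacing "
                         f"({grid.spacing_nm:.4f} nm)")
    targets = np.arange(grid.start_nm, grid.end_nm + 1e-9, step_nm)
    nearest = np.rint((targets - grid.start_nm) / grid.spacing_nm).astype(int)
    nearest = np.clip(nearest, 0, grid.n_bands - 1)
    idx = np.unique(nearest)  # dedupe, keep sorted
    return BandSelection(mode="downsample", band_indices=idx,
                         wavelengths=grid.values[idx], params={"step_nm": step_nm})


def selection_from_relieff(result, K: int, grid: WavelengthGrid) -> BandSelection:
    table = top_k_bands(result, K=K, grid=grid)
    idx = table["band_index"].to_numpy()
    return BandSelection(mode="topk", band_indices=idx, wavelengths=grid.values[idx],
                         params={"K": K})


def full_spectrum_selection(grid: WavelengthGrid) -> BandSelection:
    idx = np.arange(grid.n_bands)
    return BandSelection(mode="full", band_indices=idx, wavelengths=grid.values)


# ---------------------------------------------------------------------------
# Reduced-band study
# ---------------------------------------------------------------------------

@dataclass
class ReducedBandRow:
    mode: str
    params: dict
    n_bands: int
    seed_accuracy: float
    majority_vote_accuracy: float
    weighted_f1: float


def run_reduced_band_study(dataset: SpectralDataset, split: SplitSpec,
                           selections: list[BandSelection],
                           model: str = "linear_svm",
                           seed: int = 42,
                           include_full_baseline: bool = True) -> pd.DataFrame:
    """Refit scaler + model per band selection under one fixed hold-out split."""
    all_selections = list(selections)
    if include_full_baseline:
        all_selections.insert(0, full_spectrum_selection(dataset.grid))

    X, y = dataset.X, dataset.labels
    rows = []
    for sel in all_selections:
        if sel.band_indices.size and (sel.band_indices.min() < 0
                                      or sel.band_indices.max() >= dataset.p):
            raise ValueError(f"selection {sel.mode!r} references bands outside the grid")
        Xr = X[:, sel.band_indices]
        scaler = fit_band_scaler(Xr[split.train_idx])
        Xtr = apply_band_scaler(scaler, Xr[split.train_idx])
        Xte = apply_band_scaler(scaler, Xr[split.test_idx])
        clf = fit_baseline_classifier(Xtr, y[split.train_idx], model=model, seed=seed)
        report = evaluate(clf, Xte, y[split.test_idx])
        preds = clf.predict(Xte)
        mv_acc, _ = majority_vote_accuracy(preds, y[split.test_idx], y[split.test_idx])
        rows.append(ReducedBandRow(mode=sel.mode, params=sel.params,
                                   n_bands=sel.n_bands,
                                   seed_accuracy=report.accuracy,
                                   majority_vote_accuracy=mv_acc,
                                   weighted_f1=report.f1_weighted))
        logger.info("reduced-band %s %s: %d bands, seed acc %.4f, vote acc %.4f",
                    sel.mode, sel.params, sel.n_bands, report.accuracy, mv_acc)
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Full-pipeline runner
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "stages": list(PIPELINE_STAGES),
    "simulate": {"n_accessions": 32, "n_seeds_per_accession": 100,
                 "preset": "easy", "planted_window_nm": None,
                 "grid": {"start_nm": 423.34, "end_nm": 1022.07, "n_bands": 825}},
    "preprocess": {"sg_window": 11, "sg_order": 2, "apply_snv": False,
                   "apply_baseline": False},
    "exploratory": {"n_perm": 999},
    "pca": {"n_components": 20},
    "relieff": {"k_neighbors": 20, "top_k": 16},
    "classify": {"model": "linear_svm", "test_fraction": 0.2, "bootstrap_B": 1000},
    "reduced_band": {"window_nm": list(GREEN_WINDOW_NM),
                     "downsample_steps_nm": list(DEFAULT_DOWNSAMPLE_STEPS_NM)},
    "seed": 42,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_full_pipeline(config: dict | None = None, out_dir: str | Path = "seedspec_run",
                      dataset: SpectralDataset | None = None) -> dict:
    """Execute every stage and write outputs plus a manifest to ``out_dir``.

    ``dataset`` may replace the simulate stage to run the pipeline on
    measured spectra.  Reruns with the same config are bit-identical for the
    deterministic stages.  Returns the manifest dict.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    unknown = [s for s in cfg["stages"] if s not in PIPELINE_STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stage(s) {unknown}; valid: {list(PIPELINE_STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config": cfg, "stages_completed": [],
                      "software": {"seedspec": __version__,
                                   "python": platform.python_version()}}
    from .calibration import build_wavelength_grid

    g = cfg["simulate"]["grid"]
    grid = build_wavelength_grid(g["start_nm"], g["end_nm"], g["n_bands"])

    if dataset is None:
        sim = cfg["simulate"]
        window = sim["planted_window_nm"]
        truth = build_archetypes(sim["n_accessions"], grid, preset=sim["preset"],
                                 planted_window_nm=tuple(window) if window else None,
                                 seed=seed)
        dataset = simulate_dataset(truth, sim["n_seeds_per_accession"], grid)
        write_dataset_csv(dataset, out / "dataset_raw.csv")
    manifest["stages_completed"].append("simulate")

    pp = cfg["preprocess"]
    pre = preprocess_dataset(dataset, PreprocessConfig(
        sg_window=pp["sg_window"], sg_order=pp["sg_order"],
        apply_snv=pp["apply_snv"], apply_baseline=pp["apply_baseline"]))
    manifest["stages_completed"].append("preprocess")

    results: dict = {}
    if "exploratory" in cfg["stages"]:
        means = accession_means(pre)
        dmat = euclidean_distance_matrix(means.to_numpy())
        pd.DataFrame(dmat, index=means.index, columns=means.index).to_csv(
            out / "accession_distances.csv")
        dendro = hierarchical_cluster(dmat, list(means.index))
        (out / "dendrogram.nwk").write_text(dendro.to_newick())
        perma = permanova(pre.X, pre.labels, n_perm=cfg["exploratory"]["n_perm"], seed=seed)
        amap = ovr_association_map(pre.X, pre.labels, pre.grid)
        best_label, best_wl, best_r2 = max_association(amap)
        results["permanova"] = {"F": perma.F, "p": perma.p, "n_perm": perma.n_perm}
        results["max_association"] = {"accession": best_label,
                                      "wavelength_nm": best_wl, "r2": best_r2}
        (out / "permanova.json").write_text(json.dumps(results["permanova"], indent=2))
        pd.DataFrame(amap.r2, index=amap.labels, columns=grid.values).to_csv(
            out / "association_r2.csv")
        manifest["stages_completed"].append("exploratory")

    split = stratified_holdout_split(pre.labels,
                                     test_fraction=cfg["classify"]["test_fraction"],
                                     seed=seed)
    scaler = fit_band_scaler(pre.X[split.train_idx])
    Xtr = apply_band_scaler(scaler, pre.X[split.train_idx])
    Xte = apply_band_scaler(scaler, pre.X[split.test_idx])
    ytr, yte = pre.labels[split.train_idx], pre.labels[split.test_idx]

    if "pca" in cfg["stages"]:
        model_pca = fit_pca(pre.X, n_components=cfg["pca"]["n_components"])
        ratios = model_pca.explained_variance_ratio
        pd.DataFrame({"component": np.arange(1, len(ratios) + 1),
                      "explained_variance_ratio": ratios,
                      "cumulative": np.cumsum(ratios)}).to_csv(
            out / "pca_explained_variance.csv", index=False)
        results["pca"] = {"ratios_first3": ratios[:3].tolist(),
                          "cumulative_first3": cumulative_variance(ratios, min(3, len(ratios)))}
        manifest["stages_completed"].append("pca")

    relief = None
    if "relieff" in cfg["stages"]:
        # ranking consumes preprocessed reflectance (already in [0, 1]), train rows only
        relief = relieff_weights(pre.X[split.train_idx], ytr,
                                 k=cfg["relieff"]["k_neighbors"], seed=seed,
                                 default_top_k=cfg["relieff"]["top_k"])
        table = top_k_bands(relief, K=cfg["relieff"]["top_k"], grid=grid)
        weights_table = pd.DataFrame({
            "wavelength_nm": grid.values, "weight": relief.weights,
            "rank": np.argsort(relief.ranking)})
        weights_table.to_csv(out / "relieff_weights.csv", index=False)
        table.to_csv(out / "relieff_topk.csv", index=False)
        results["relieff_topk_nm"] = table["wavelength_nm"].tolist()
        manifest["stages_completed"].append("relieff")

    if "classify" in cfg["stages"]:
        clf = fit_baseline_classifier(Xtr, ytr, model=cfg["classify"]["model"], seed=seed)
        report = evaluate(clf, Xte, yte)
        preds = clf.predict(Xte)
        mv_acc, mv_outcomes = majority_vote_accuracy(preds, yte, yte)
        flags = (preds == yte).astype(float)
        ci = cluster_bootstrap_ci(flags, yte, B=cfg["classify"]["bootstrap_B"], seed=seed)
        n_correct_acc = sum(o["correct"] for o in mv_outcomes.values())
        binom_ci = exact_binomial_ci(n_correct_acc, len(mv_outcomes))
        results["classification"] = {
            "model": cfg["classify"]["model"],
            "seed_accuracy": report.accuracy,
            "weighted_f1": report.f1_weighted,
            "total_errors": report.total_errors,
            "majority_vote_accuracy": mv_acc,
            "bootstrap_ci_95": [ci.low, ci.high],
            "accession_binomial_ci_95": list(binom_ci),
        }
        (out / "classification_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        pd.DataFrame(report.confusion, index=report.class_labels,
                     columns=report.class_labels).to_csv(out / "confusion.csv")
        manifest["stages_completed"].append("classify")

    if "reduced_band" in cfg["stages"]:
        rb = cfg["reduced_band"]
        selections = [select_window(grid, *rb["window_nm"])]
        if relief is not None:
            selections.insert(0, selection_from_relieff(relief, cfg["relieff"]["top_k"], grid))
        selections += [uniform_downsample(grid, s) for s in rb["downsample_steps_nm"]]
        table = run_reduced_band_study(pre, split, selections,
                                       model=cfg["classify"]["model"], seed=seed)
        table.to_csv(out / "reduced_band_study.csv", index=False)
        results["reduced_band"] = table.drop(columns=["params"]).to_dict(orient="records")
        manifest["stages_completed"].append("reduced_band")

    manifest["results"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %d stages -> %s",
                len(manifest["stages_completed"]), out)
    return manifest
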