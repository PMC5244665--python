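"""End-to-end pipeline orchestration with provenance.

Stages: simulate (or load) -> T2 screen -> fit all candidate models ->
information-criterion selection -> derived maps -> optional MCMC on
selected voxels.  Every run writes a JSON manifest listing the
artefacts with SHA-256 checksums and the seeds/config that produced
them; a stage is skipped when its outputs already exist and are newer
than its inputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import fitting, maps as maps_mod, selection, synthgen, t2screen
from .compartments import MODELS, get_model
from .fitting import NoiseEstimate
from .protocol import build_full_protocol, read_scheme, write_scheme

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_MODELS = tuple(MODELS)


@dataclass
class RunConfig:
    out_dir: str
    dwi_path: Optional[str] = None
    scheme_path: Optional[str] = None
    multiecho_path: Optional[str] = None
    mask_path: Optional[str] = None
    simulate: bool = True
    models: tuple = DEFAULT_MODELS
    criterion: str = "bic"
    n_starts: int = 5
    seed: int = 0
    snr: float = 100.0
    phantom_shape: tuple = (64, 64, 4)
    max_fit_voxels: Optional[int] = None  # subsample for quick runs
    mcmc_voxels: int = 0
    screen_threshold: float = 0.90

    def validate(self):
        for m in self.models:
            get_model(m)
        if self.criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        if not self.simulate and (self.dwi_path is None or self.scheme_path is None):
            raise ValueError("without --simulate, provide DWI and scheme paths")


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _newer_than(outputs, inputs):
    if not all(os.path.exists(p) for p in outputs):
        return False
    newest_in = max((os.path.getmtime(p) for p in inputs), default=0.0)
    return min(os.path.getmtime(p) for p in outputs) >= newest_in


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "artefacts": {},
    }
    rng_seed = config.seed

    # ---- stage: data ------------------------------------------------
    t0 = time.time()
    scheme_file = os.path.join(out, "scheme.txt")
    dwi_file = os.path.join(out, "dwi.nii.gz")
    echo_file = os.path.join(out, "multiecho.nii.gz")
    if config.simulate:
        phantom = synthgen.make_phantom(shape=tuple(config.phantom_shape),
                                        seed=rng_seed)
        scheme = build_full_protocol()
        sigma = 1.0 / config.snr
        if not _newer_than([scheme_file, dwi_file, echo_file], []):
            dwi = synthgen.simulate_signals(phantom, scheme, sigma, seed=rng_seed + 1)
            echo = synthgen.simulate_multiecho(
                phantom, sigma=sigma, seed=rng_seed + 2
            )
            write_scheme(scheme, scheme_file)
            maps_mod.save_nifti(dwi, dwi_file, phantom.voxel_size)
            maps_mod.save_nifti(echo, echo_file, phantom.voxel_size)
        else:
            dwi, _ = maps_mod.load_nifti(dwi_file)
            echo, _ = maps_mod.load_nifti(echo_file)
        tissue = phantom.tissue_mask
        fat = phantom.fat_mask
        labels_file = os.path.join(out, "labels.nii.gz")
        maps_mod.save_nifti(phantom.labels.astype(float), labels_file,
                            phantom.voxel_size)
        voxel_size = phantom.voxel_size
        noise = NoiseEstimate(sigma, source="simulation ground truth")
    else:
        scheme = read_scheme(config.scheme_path)
        dwi, voxel_size = maps_mod.load_nifti(config.dwi_path)
        if dwi.shape[3] != len(scheme):
            raise ValueError(
                f"DWI has {dwi.shape[3]} volumes but scheme has "
                f"{len(scheme)} measurements"
            )
        if config.mask_path:
            m, _ = maps_mod.load_nifti(config.mask_path)
            tissue = m > 0
        else:
            tissue = np.ones(dwi.shape[:3], bool)
        fat = np.zeros_like(tissue)
        echo = None
        bg = dwi[~tissue][:, 0] if (~tissue).any() else dwi[..., 0].ravel()
        noise = fitting.estimate_noise_sigma(bg.ravel())
    manifest["stages"]["data"] = {"seconds": time.time() - t0,
                                  "n_measurements": len(scheme)}

    # ---- stage: screen ----------------------------------------------
    t0 = time.time()
    if echo is not None:
        screen = t2screen.screen_volume(
            echo, synthgen.DEFAULT_ECHO_TIMES, tissue, fat_mask=fat,
            threshold=config.screen_threshold,
        )
        fit_mask = screen.include
        screen_file = os.path.join(out, "screen_mask.nii.gz")
        maps_mod.save_nifti(screen.reason.astype(float), screen_file, voxel_size)
    else:
        fit_mask = tissue & ~fat
    manifest["stages"]["screen"] = {
        "seconds": time.time() - t0,
        "n_included": int(fit_mask.sum()),
    }

    # ---- stage: fit all models --------------------------------------
    t0 = time.time()
    mask = fit_mask.copy()
    if config.max_fit_voxels is not None and mask.sum() > config.max_fit_voxels:
        idx = np.argwhere(mask)
        keep = np.random.default_rng(rng_seed + 3).choice(
            len(idx), size=config.max_fit_voxels, replace=False
        )
        mask = np.zeros_like(mask)
        mask[tuple(idx[keep].T)] = True
    fits_file = os.path.join(out, "fits.csv")
    all_fits = []
    for name in config.models:
        df = fitting.fit_volume(
            dwi, scheme, name, noise, mask=mask,
            n_starts=config.n_starts, seed=rng_seed + 10,
        )
        all_fits.append(df)
    fits = pd.concat(all_fits, ignore_index=True)
    fits.to_csv(fits_file, index=False)
    manifest["stages"]["fit"] = {
        "seconds": time.time() - t0,
        "n_voxels": int(mask.sum()),
        "models": list(config.models),
        "n_failed": int((~fits["converged"]).sum()),
    }

    # ---- stage: select ----------------------------------------------
    t0 = time.time()
    sel = selection.select_models(fits)
    sel_file = os.path.join(out, "selection.csv")
    sel.to_csv(sel_file, index=False)
    summary = selection.summarise_relative(fits)
    summary_file = os.path.join(out, "relative_criteria.csv")
    summary.to_csv(summary_file, index=False)
    best_col = f"best_{config.criterion}"
    legend = {name: i + 1 for i, name in enumerate(sorted(config.models))}
    best_map = np.zeros(dwi.shape[:3])
    for _, row in sel.iterrows():
        best_map[int(row["i"]), int(row["j"]), int(row["k"])] = legend[row[best_col]]
    best_file = os.path.join(out, "best_model.nii.gz")
    maps_mod.save_nifti(best_map, best_file, voxel_size)
    legend_file = os.path.join(out, "best_model_legend.json")
    with open(legend_file, "w") as fh:
        json.dump(legend, fh, indent=1)
    manifest["stages"]["select"] = {"seconds": time.time() - t0}

    # ---- stage: maps ------------------------------------------------
    t0 = time.time()
    written = []
    for name in config.models:
        sub = fits[fits["model"] == name]
        sub = sub.dropna(axis=1, how="all")  # drop other models' columns
        pm = maps_mod.maps_from_fits(
            sub, dwi.shape[:3], voxel_size,
            {"model": name, "seed": rng_seed},
        )
        if {"D1", "D2", "theta", "phi"} <= set(pm.maps):
            fa, rgb = maps_mod.colour_fa(
                pm.maps["D1"], pm.maps["D2"], pm.maps["theta"], pm.maps["phi"]
            )
            pm.maps["FA"] = fa
            pm.maps["colourFA"] = rgb
            maps_mod.save_colour_fa_png(
                rgb, os.path.join(out, f"{name.replace('-', '_')}_colourFA.png")
            )
        written += pm.save(out, prefix=f"{name.replace('-', '_')}_")
    manifest["stages"]["maps"] = {"seconds": time.time() - t0}

    # ---- stage: mcmc ------------------------------------------------
    if config.mcmc_voxels > 0:
        from .posterior import MCMCSettings, sample_posterior

        t0 = time.time()
        crit_model = sel[best_col].mode().iloc[0]
        spec = get_model(crit_model)
        sub = fits[fits["model"] == crit_model].head(config.mcmc_voxels)
        mcmc_files = []
        for _, row in sub.iterrows():
            data = dwi[int(row["i"]), int(row["j"]), int(row["k"])]
            init = np.array([row[p] for p in spec.free_params])
            ps = sample_posterior(
                data, scheme, spec, noise, init, seed=rng_seed + 20
            )
            f = os.path.join(
                out, f"mcmc_{int(row['i'])}_{int(row['j'])}_{int(row['k'])}.csv"
            )
            ps.to_dataframe().to_csv(f, index=False)
            mcmc_files.append(f)
        manifest["stages"]["mcmc"] = {
            "seconds": time.time() - t0,
            "files": mcmc_files,
        }

    for root, _, files in os.walk(out):
        for f in files:
            if f == "manifest.json":
                continue
            p = os.path.join(root, f)
            manifest["artefacts"][os.path.relpath(p, out)] = _sha256(p)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
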