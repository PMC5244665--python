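"""Derived parameter maps and NIfTI I/O.

Builds the quantitative maps reported for each fitted sample: ADC from
the Ball (mono-exponential) model, intracellular volume fraction f_I,
cell radius R, fractional anisotropy (FA) of the Zeppelin part of a
two-compartment fit (the isotropic restricted compartment is removed
from the FA calculation), and direction-encoded colour FA.  Also
implements in-plane downsampling by block averaging of the raw
magnitude data, used to study how anisotropy washes out at coarser
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .compartments import zeppelin_axis
from .fitting import NoiseEstimate, fit_volume

__all__ = [
    "ParameterMaps",
    "adc_map",
    "maps_from_fits",
    "zeppelin_fa",
    "colour_fa",
    "downsample",
    "save_nifti",
    "load_nifti",
]


@dataclass
class ParameterMaps:
    """Named 3-D parameter arrays on a common grid.

    Excluded voxels carry NaN.  ``voxel_size`` in mm; ``provenance``
    records model name, seeds and settings.
    """

    maps: dict
    voxel_size: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    def save(self, directory, prefix: str = "") -> list:
        """Write one NIfTI per map; returns the written paths."""
        import os

        paths = []
        for name, arr in self.maps.items():
            p = os.path.join(directory, f"{prefix}{name}.nii.gz".replace("/", "_"))
            save_nifti(arr, p, self.voxel_size)
            paths.append(p)
        return paths


def save_nifti(array, path, voxel_size=(1.0, 1.0, 1.0)):
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.header.get_zooms()[:3]


def maps_from_fits(
    fits: pd.DataFrame, shape, voxel_size, provenance=None
) -> ParameterMaps:
    """Scatter a tidy per-voxel fit table into NaN-filled 3-D maps."""
    skip = {"i", "j", "k", "model", "converged"}
    cols = [c for c in fits.columns if c not in skip]
    maps = {c: np.full(shape, np.nan) for c in cols}
    ii = fits["i"].to_numpy(int)
    jj = fits["j"].to_numpy(int)
    kk = fits["k"].to_numpy(int)
    for c in cols:
        maps[c][ii, jj, kk] = fits[c].to_numpy(float)
    return ParameterMaps(maps, tuple(voxel_size), provenance or {})


def adc_map(
    data4d,
    scheme,
    mask,
    noise: NoiseEstimate,
    voxel_size=(1.0, 1.0, 1.0),
    n_starts: int = 3,
    seed: int = 0,
) -> ParameterMaps:
    """Apparent diffusion coefficient map from the mono-exponential Ball fit.

    ADC is reported in um^2/ms (= 1e-3 mm^2/s), the unit used for tissue
    diffusivities throughout.
    """
    fits = fit_volume(
        data4d, scheme, "Ball", noise, mask=mask, n_starts=n_starts, seed=seed
    )
    pm = maps_from_fits(
        fits,
        np.asarray(data4d).shape[:3],
        voxel_size,
        {"model": "Ball", "seed": seed, "n_starts": n_starts},
    )
    pm.maps["ADC"] = pm.maps.pop("D1")
    return pm


def zeppelin_fa(D1, D2):
    """FA of an axially symmetric tensor with eigenvalues (D1, D2, D2).

    Scale-invariant; 0 for isotropic (D1 = D2), 1 in the stick limit
    (D2 = 0).  Returns NaN where both eigenvalues vanish.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if np.any(D1 < 0) or np.any(D2 < 0):
        raise ValueError("eigenvalues must be non-negative")
    md = (D1 + 2 * D2) / 3.0
    num = np.sqrt((D1 - md) ** 2 + 2 * (D2 - md) ** 2)
    den = np.sqrt(D1**2 + 2 * D2**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den == 0, np.nan, fa)
    return float(fa) if fa.ndim == 0 else fa


def colour_fa(D1, D2, theta, phi):
    """Direction-encoded colour FA: RGB = |n| * FA per voxel.

    ``n`` is the primary axis of the Zeppelin part; antipodal
    orientations map to identical colours.  Returns (fa, rgb) where rgb
    stacks the colour channels on the last axis.
    """
    fa = zeppelin_fa(D1, D2)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    n = np.stack(
        [np.abs(st * np.cos(phi)), np.abs(st * np.sin(phi)), np.abs(np.cos(theta))],
        axis=-1,
    )
    rgb = n * np.asarray(fa)[..., None]
    return fa, rgb


def save_colour_fa_png(rgb, path, axis: int = 2):
    """Write a PNG mosaic of the colour-FA slices for quick inspection.

    ``rgb`` is a 4-D array (x, y, z, 3) with channels in [0, 1]; slices
    along ``axis`` are tiled horizontally.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    rgb = np.nan_to_num(np.asarray(rgb, dtype=float))
    rgb = np.clip(rgb, 0.0, 1.0)
    slices = [np.take(rgb, i, axis=axis) for i in range(rgb.shape[axis])]
    mosaic = np.concatenate(slices, axis=1)
    plt.imsave(str(path), mosaic)


def downsample(volume_4d, factors):
    """Block-average a 4-D magnitude volume by integer spatial factors.

    ``factors`` = (fy, fx, fz).  Dimensions not divisible by their
    factor are padded by edge replication (with a warning) before
    averaging.  The measurement axis is untouched.
    """
    vol = np.asarray(volume_4d, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, measurement)")
    fy, fx, fz = (int(f) for f in factors)
    if min(fy, fx, fz) < 1:
        raise ValueError("factors must be positive integers")
    pads = []
    for dim, f in zip(vol.shape[:3], (fy, fx, fz)):
        rem = (-dim) % f
        pads.append((0, rem))
    if any(p[1] for p in pads):
        warnings.warn(
            f"volume shape {vol.shape[:3]} not divisible by {factors}; "
            "padding by edge replication",
            stacklevel=2,
        )
        vol = np.pad(vol, pads + [(0, 0)], mode="edge")
    ny, nx, nz, nm = vol.shape
    out = vol.reshape(ny // fy, fy, nx // fx, fx, nz // fz, fz, nm).mean(
        axis=(1, 3, 5)
    )
    return out
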