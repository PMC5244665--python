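"""T2-spectrum screening of voxels before diffusion fitting.

The diffusion models assume mono-exponential T2 decay.  A multi-echo
acquisition probes this: each voxel's echo train is decomposed into a
non-negative spectrum of relaxation times by NNLS,

    min_{a >= 0} || S(TE_i) - sum_j a_j exp(-TE_i / T2_j) ||^2

over a log-spaced T2 grid.  A voxel passes the screen when the main
spectral peak (the maximal contiguous run of non-negligible amplitudes
containing the global maximum) holds at least 90% of the total spectral
area; voxels failing that, or flagged as fat/background, are excluded
from fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "T2Spectrum",
    "ScreenMask",
    "default_t2_grid",
    "nnls_t2_spectrum",
    "screen_voxels",
    "screen_volume",
    "SCREEN_CODES",
]

#: Integer codes of the screening mask.
SCREEN_CODES = {"background": 0, "include": 1, "fat": 2, "non-mono-T2": 3}

_PEAK_FLOOR = 1e-6  # amplitudes below this fraction of the max count as zero


def default_t2_grid(n: int = 120, t2_min: float = 1e-3, t2_max: float = 3.0):
    """Log-spaced relaxation-time grid in seconds (default 1 ms .. 3 s)."""
    return np.geomspace(t2_min, t2_max, n)


@dataclass
class T2Spectrum:
    """NNLS amplitude spectrum over a T2 grid."""

    t2_grid: np.ndarray
    amplitudes: np.ndarray
    residual: float

    def peaks(self):
        """Maximal contiguous runs of non-negligible amplitude.

        Returns a list of (slice, area_fraction); fractions sum to 1
        when any amplitude is nonzero.
        """
        a = self.amplitudes
        total = a.sum()
        if total == 0:
            return []
        nz = a > _PEAK_FLOOR * a.max()
        out = []
        start = None
        for i, flag in enumerate(np.append(nz, False)):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                sl = slice(start, i)
                out.append((sl, float(a[sl].sum() / total)))
                start = None
        return out

    @property
    def main_peak_fraction(self) -> float:
        """Area fraction of the contiguous peak containing the global max."""
        a = self.amplitudes
        if a.sum() == 0:
            return 0.0
        imax = int(np.argmax(a))
        for sl, frac in self.peaks():
            if sl.start <= imax < sl.stop:
                return frac
        return 0.0  # pragma: no cover

    @property
    def main_peak_t2(self) -> float:
        """Amplitude-weighted T2 (s) of the main peak."""
        a = self.amplitudes
        imax = int(np.argmax(a))
        for sl, _ in self.peaks():
            if sl.start <= imax < sl.stop:
                w = a[sl]
                return float(np.sum(w * self.t2_grid[sl]) / w.sum())
        return float("nan")  # pragma: no cover


def nnls_t2_spectrum(
    echo_signals,
    echo_times,
    t2_grid=None,
    regularisation: float = 0.0,
) -> T2Spectrum:
    """Decompose one voxel's echo decay into a non-negative T2 spectrum.

    ``echo_times`` in ms; ``t2_grid`` in s (default 120 log-spaced
    points in [1 ms, 3 s]).  ``regularisation`` adds Tikhonov rows
    sqrt(lambda) * I to the design (0 = plain NNLS).
    """
    s = np.asarray(echo_signals, dtype=float).ravel()
    te = np.asarray(echo_times, dtype=float).ravel() * 1e-3
    if s.shape != te.shape:
        raise ValueError("echo_signals and echo_times must have equal length")
    if len(s) < 8:
        raise ValueError("need at least 8 echoes for a T2 spectrum")
    if np.all(s == 0):
        raise ValueError("all-zero echo signal")
    if t2_grid is None:
        # floor the grid at the first echo time: faster components are
        # unobservable and their near-zero design columns otherwise soak
        # up noise with spuriously huge amplitudes
        grid = default_t2_grid(t2_min=max(1e-3, float(te.min())))
    else:
        grid = np.asarray(t2_grid, dtype=float)
    A = np.exp(-te[:, None] / grid[None, :])
    y = s
    if regularisation > 0:
        A = np.vstack([A, np.sqrt(regularisation) * np.eye(len(grid))])
        y = np.concatenate([s, np.zeros(len(grid))])
    ampl, rnorm = nnls(A, y)
    return T2Spectrum(grid, ampl, float(rnorm))


@dataclass
class ScreenMask:
    """Per-voxel include/exclude decision with a reason code."""

    include: np.ndarray   # bool
    reason: np.ndarray    # int, see SCREEN_CODES

    def fraction_excluded(self, code: str) -> float:
        considered = self.reason != SCREEN_CODES["background"]
        if considered.sum() == 0:
            return 0.0
        return float((self.reason == SCREEN_CODES[code]).sum() / considered.sum())


def screen_voxels(
    spectra,
    fat_mask=None,
    background_mask=None,
    threshold: float = 0.90,
) -> ScreenMask:
    """Combine T2 spectra with fat/background masks into a screen mask.

    ``spectra`` is a sequence of :class:`T2Spectrum` (or None for
    background voxels).  Include = main peak fraction >= threshold AND
    not fat AND not background.
    """
    n = len(spectra)
    fat = np.zeros(n, bool) if fat_mask is None else np.asarray(fat_mask, bool).ravel()
    bg = (
        np.zeros(n, bool)
        if background_mask is None
        else np.asarray(background_mask, bool).ravel()
    )
    include = np.zeros(n, dtype=bool)
    reason = np.zeros(n, dtype=np.int16)
    for i, sp in enumerate(spectra):
        if bg[i] or sp is None:
            reason[i] = SCREEN_CODES["background"]
        elif fat[i]:
            reason[i] = SCREEN_CODES["fat"]
        elif sp.main_peak_fraction >= threshold:
            include[i] = True
            reason[i] = SCREEN_CODES["include"]
        else:
            reason[i] = SCREEN_CODES["non-mono-T2"]
    return ScreenMask(include, reason)


def screen_volume(
    echo_data,
    echo_times,
    tissue_mask,
    fat_mask=None,
    threshold: float = 0.90,
    t2_grid=None,
) -> ScreenMask:
    """Screen a 4-D multi-echo volume; returns masks shaped like the volume.

    ``tissue_mask`` marks voxels to consider (others are background);
    ``fat_mask`` marks voxels excluded as fat without spectral analysis.
    """
    echo_data = np.asarray(echo_data, dtype=float)
    shape = echo_data.shape[:3]
    tissue = np.asarray(tissue_mask, bool)
    fat = np.zeros(shape, bool) if fat_mask is None else np.asarray(fat_mask, bool)
    include = np.zeros(shape, dtype=bool)
    reason = np.zeros(shape, dtype=np.int16)
    for i, j, k in np.argwhere(tissue):
        if fat[i, j, k]:
            reason[i, j, k] = SCREEN_CODES["fat"]
            continue
        sp = nnls_t2_spectrum(echo_data[i, j, k], echo_times, t2_grid=t2_grid)
        if sp.main_peak_fraction >= threshold:
            include[i, j, k] = True
            reason[i, j, k] = SCREEN_CODES["include"]
        else:
            reason[i, j, k] = SCREEN_CODES["non-mono-T2"]
    return ScreenMask(include, reason)
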