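"""Synthetic breast-tissue phantom and forward signal simulation.

The phantom emulates the microstructural environments seen in ex vivo
breast specimens on a regular imaging grid (default 64 x 64 x 4 voxels
at 0.25 x 0.25 x 0.5 mm):

* **tumour-cellular** -- densely packed cells; generated by a
  Zeppelin-Sphere model with intracellular fraction around 0.44 and cell
  radii in the 6-9 um range.
* **stroma-aligned** -- fibrous collagen stroma; Zeppelin-Ball with high
  anisotropy and orientations coherent over ~1 mm patches.
* **mucinous** -- low-cellularity mucin pools; free isotropic diffusion
  (Ball) with high diffusivity.
* **necrotic** -- Ball diffusion but bi-exponential T2 decay, so these
  voxels should fail the mono-exponential T2 screen.
* **fat** -- excluded from fitting by the fat mask.

Forward simulation evaluates the generating compartment model for each
voxel over an acquisition scheme and corrupts the signal with Rician
noise (magnitude of a complex Gaussian).  A Monte-Carlo random walk with
a reflecting spherical boundary provides an independent oracle for the
GPD restricted-diffusion series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .compartments import PrecomputedScheme, get_model
from .protocol import AcquisitionScheme, Measurement

__all__ = [
    "REGION_LABELS",
    "REGION_MODELS",
    "Phantom",
    "make_phantom",
    "simulate_signals",
    "simulate_multiecho",
    "add_rician_noise",
    "mc_sphere_oracle",
    "DEFAULT_ECHO_TIMES",
]

#: Integer codes for the phantom regions.
REGION_LABELS = {
    "background": 0,
    "tumour-cellular": 1,
    "stroma-aligned": 2,
    "mucinous": 3,
    "necrotic": 4,
    "fat": 5,
}
_LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}

#: Generating signal model per region (background/fat carry no model fit).
REGION_MODELS = {
    "tumour-cellular": "Zeppelin-Sphere",
    "stroma-aligned": "Zeppelin-Ball",
    "mucinous": "Ball",
    "necrotic": "Ball",
    "fat": "Ball",
}

#: 32 echoes at 5 ms spacing, matching the multi-echo T2 acquisition.
DEFAULT_ECHO_TIMES = np.arange(1, 33) * 5.0  # ms

_PARAM_NAMES = (
    "D1", "D2", "D3", "theta", "phi", "alpha", "D_I", "R", "f_I", "S0", "T2",
)


@dataclass
class Phantom:
    """Ground-truth parameter maps with region labels.

    ``params`` maps parameter name -> 3-D float array (NaN where the
    parameter does not apply); necrotic voxels additionally carry the
    bi-exponential T2 mixture (``t2_short``, ``t2_long``,
    ``t2_short_fraction``) used by the multi-echo simulator.
    """

    labels: np.ndarray
    params: dict
    voxel_size: tuple
    seed: int
    t2_short: float = 0.030      # s
    t2_long: float = 0.200       # s
    t2_short_fraction: float = 0.6

    @property
    def shape(self):
        return self.labels.shape

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == REGION_LABELS[name]

    @property
    def tissue_mask(self) -> np.ndarray:
        """Voxels eligible for fitting: neither background nor fat."""
        return (self.labels != REGION_LABELS["background"]) & (
            self.labels != REGION_LABELS["fat"]
        )

    @property
    def fat_mask(self) -> np.ndarray:
        return self.region_mask("fat")

    def region_name(self, code: int) -> str:
        return _LABEL_NAMES[code]


def _ellipse_mask(shape2d, center, radii):
    yy, xx = np.mgrid[: shape2d[0], : shape2d[1]]
    return ((yy - center[0]) / radii[0]) ** 2 + (
        (xx - center[1]) / radii[1]
    ) ** 2 <= 1.0


def _patch_orientations(shape, patch: int, rng):
    """Random axis per in-plane patch of `patch` voxels, coherent within it."""
    ny, nx, nz = shape
    py, px = -(-ny // patch), -(-nx // patch)
    v = rng.standard_normal((py, px, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    v[v[..., 2] < 0] *= -1  # upper hemisphere representative
    theta = np.arccos(np.clip(v[..., 2], -1, 1))
    phi = np.arctan2(v[..., 1], v[..., 0]) % (2 * np.pi)
    theta_full = np.repeat(np.repeat(theta, patch, 0), patch, 1)[:ny, :nx]
    phi_full = np.repeat(np.repeat(phi, patch, 0), patch, 1)[:ny, :nx]
    return (
        np.broadcast_to(theta_full[..., None], shape).copy(),
        np.broadcast_to(phi_full[..., None], shape).copy(),
    )


def make_phantom(
    shape=(64, 64, 4),
    voxel_size=(0.25, 0.25, 0.5),
    seed: int = 0,
    snr_reference: float = 1.0,
) -> Phantom:
    """Build the default structured phantom.

    Region geometry is a set of non-overlapping ellipses inside an
    elliptical "specimen" on every slice; the remaining specimen voxels
    are aligned stroma.  All parameter draws are deterministic given
    ``seed``.  ``snr_reference`` sets S0 for every voxel.
    """
    ny, nx, nz = shape
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int16)

    specimen = _ellipse_mask((ny, nx), (ny / 2, nx / 2), (ny * 0.45, nx * 0.45))
    regions2d = {
        "tumour-cellular": _ellipse_mask((ny, nx), (ny * 0.34, nx * 0.34), (ny * 0.16, nx * 0.14)),
        "mucinous": _ellipse_mask((ny, nx), (ny * 0.34, nx * 0.68), (ny * 0.12, nx * 0.11)),
        "necrotic": _ellipse_mask((ny, nx), (ny * 0.68, nx * 0.34), (ny * 0.11, nx * 0.10)),
        "fat": _ellipse_mask((ny, nx), (ny * 0.68, nx * 0.68), (ny * 0.12, nx * 0.11)),
    }
    for name, m2d in regions2d.items():
        m2d &= specimen
        overlap = labels[..., 0][m2d]
        if np.any(overlap != 0):
            raise ValueError(f"region {name} overlaps a previously placed region")
        for z in range(nz):
            labels[..., z][m2d] = REGION_LABELS[name]
    for z in range(nz):
        sl = labels[..., z]
        sl[specimen & (sl == 0)] = REGION_LABELS["stroma-aligned"]

    params = {k: np.full(shape, np.nan) for k in _PARAM_NAMES}
    params["S0"][:] = np.nan

    def draw(mask, name, lo, hi):
        params[name][mask] = rng.uniform(lo, hi, size=int(mask.sum()))

    # tumour-cellular: Zeppelin-Sphere
    m = labels == REGION_LABELS["tumour-cellular"]
    draw(m, "D1", 0.80, 1.10)
    draw(m, "D2", 0.45, 0.70)
    draw(m, "D_I", 0.80, 1.20)
    draw(m, "R", 6.0, 9.0)
    draw(m, "f_I", 0.35, 0.55)
    draw(m, "T2", 0.050, 0.090)
    th, ph = _patch_orientations(shape, 4, rng)
    params["theta"][m] = th[m]
    params["phi"][m] = ph[m]

    # stroma-aligned: Zeppelin-Ball, high anisotropy, 1-mm coherent patches
    m = labels == REGION_LABELS["stroma-aligned"]
    draw(m, "D1", 1.60, 2.20)
    draw(m, "D2", 0.20, 0.45)
    draw(m, "D_I", 0.50, 1.00)
    draw(m, "f_I", 0.05, 0.20)
    draw(m, "T2", 0.040, 0.080)
    th, ph = _patch_orientations(shape, 4, rng)
    params["theta"][m] = th[m]
    params["phi"][m] = ph[m]

    # mucinous: free high-diffusivity Ball, essentially no intracellular water
    m = labels == REGION_LABELS["mucinous"]
    draw(m, "D1", 1.20, 1.60)
    params["f_I"][m] = 0.0
    params["R"][m] = 20.0  # upper bound: equivalent to unrestricted
    draw(m, "T2", 0.120, 0.200)

    # necrotic: Ball diffusion, bi-exponential T2 (flagged for screening)
    m = labels == REGION_LABELS["necrotic"]
    draw(m, "D1", 0.90, 1.40)
    params["f_I"][m] = 0.0
    draw(m, "T2", 0.080, 0.120)  # effective mono T2 used for DWI synthesis

    # fat: slow isotropic diffusion, short T2; excluded by the fat mask
    m = labels == REGION_LABELS["fat"]
    draw(m, "D1", 0.03, 0.08)
    params["f_I"][m] = 0.0
    draw(m, "T2", 0.030, 0.060)

    params["S0"][labels > 0] = float(snr_reference)
    return Phantom(labels, params, tuple(voxel_size), int(seed))


def add_rician_noise(signal, sigma, rng, n_avg=None):
    """Magnitude of (S + g1, g2) with iid Gaussian g of SD sigma.

    ``sigma`` may be scalar or broadcastable to ``signal``; when
    ``n_avg`` is given, the effective SD is divided by sqrt(n_avg),
    modelling averaged magnitude images.
    """
    sigma = np.asarray(sigma, dtype=float)
    if n_avg is not None:
        sigma = sigma / np.sqrt(np.asarray(n_avg, dtype=float))
    g1 = rng.standard_normal(np.shape(signal))
    g2 = rng.standard_normal(np.shape(signal))
    return np.sqrt((signal + sigma * g1) ** 2 + (sigma * g2) ** 2)


def _forward_region(phantom, mask, model_name, cache):
    """Noiseless signals (V, n) for all voxels of one region."""
    spec = get_model(model_name)
    idx = np.argwhere(mask)
    V, n = len(idx), cache.n
    out = np.zeros((V, n))
    p = {k: phantom.params[k][mask] for k in _PARAM_NAMES}
    b = cache.b_mm * 1e-3  # so b*D dimensionless with D in um^2/ms
    # extracellular attenuation
    if spec.extracellular_shape == "Ball":
        ec = np.exp(-np.outer(p["D1"], b))
    elif spec.extracellular_shape == "Zeppelin":
        st = np.sin(p["theta"])
        axes = np.stack(
            [st * np.cos(p["phi"]), st * np.sin(p["phi"]), np.cos(p["theta"])], axis=1
        )
        c2 = (axes @ cache.directions.T) ** 2  # (V, n)
        ec = np.exp(-b[None, :] * ((p["D1"] - p["D2"])[:, None] * c2 + p["D2"][:, None]))
    else:  # pragma: no cover - no default region generates a full Tensor
        raise NotImplementedError("tensor-generating regions are not configured")
    if not spec.two_compartment:
        att = ec
    else:
        if spec.intracellular_shape == "Ball":
            ic = np.exp(-np.outer(p["D_I"], b))
        else:
            ic = _sphere_attenuation_voxels(p["D_I"], p["R"], cache)
        f = p["f_I"][:, None]
        att = (1.0 - f) * ec + f * ic
    decay = p["S0"][:, None] * np.exp(-cache.TE_si[None, :] / p["T2"][:, None])
    out[:] = decay * att
    return idx, out


def _sphere_attenuation_voxels(D_I, R, cache):
    """GPD attenuation for per-voxel (D_I, R), vectorised over voxels."""
    from .compartments import _GPD_ROOTS  # noqa: PLC0415

    V = len(D_I)
    U = len(cache.uniq_G)
    D_si = np.asarray(D_I) * 1e-9
    R_si = np.asarray(R) * 1e-6
    am = _GPD_ROOTS
    alpha = am[None, :] / R_si[:, None]            # (V, M)
    a2D = alpha**2 * D_si[:, None]                 # (V, M) 1/s
    d = cache.uniq_delta[None, :, None]            # (1, U, 1)
    Dl = cache.uniq_Delta[None, :, None]
    e = a2D[:, None, :]
    num = (
        2.0 * d * e
        - 2.0
        + 2.0 * np.exp(-e * d)
        + 2.0 * np.exp(-e * Dl)
        - np.exp(-e * (Dl - d))
        - np.exp(-e * (Dl + d))
    )
    denom = (D_si[:, None] ** 2) * alpha**6 * (alpha**2 * R_si[:, None] ** 2 - 2.0)
    ln_E = -2.0 * cache.gamma**2 * cache.uniq_G[None, :] ** 2 * np.sum(
        num / denom[:, None, :], axis=2
    )
    return np.exp(ln_E)[:, cache.uniq_inverse]


def simulate_signals(
    phantom: Phantom,
    scheme: AcquisitionScheme,
    sigma: float,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a 4-D DWI volume over ``scheme`` with Rician noise SD ``sigma``.

    Noise is scaled per measurement by 1/sqrt(n_avg).  ``sigma = 0``
    returns the noiseless forward model.  Background voxels contain pure
    noise.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    cache = PrecomputedScheme(scheme)
    vol = np.zeros(phantom.shape + (cache.n,))
    for name, model in REGION_MODELS.items():
        mask = phantom.region_mask(name)
        if not mask.any():
            continue
        idx, sig = _forward_region(phantom, mask, model, cache)
        vol[idx[:, 0], idx[:, 1], idx[:, 2], :] = sig
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return vol
    return add_rician_noise(vol, sigma, rng, n_avg=cache.n_avg)


def simulate_multiecho(
    phantom: Phantom,
    echo_times=DEFAULT_ECHO_TIMES,
    sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate the multi-echo T2 volume (echo times in ms).

    Non-necrotic tissue decays mono-exponentially with the voxel's T2;
    necrotic voxels decay as a two-component mixture
    (t2_short_fraction at t2_short, remainder at t2_long).
    """
    echo_times = np.asarray(echo_times, dtype=float)
    if echo_times.size < 2:
        raise ValueError("need at least two echoes")
    te_s = echo_times * 1e-3
    shape = phantom.shape
    vol = np.zeros(shape + (len(te_s),))
    tissue = phantom.labels > 0
    S0 = phantom.params["S0"]
    T2 = phantom.params["T2"]
    mono = tissue & ~phantom.region_mask("necrotic")
    vol[mono] = S0[mono, None] * np.exp(-te_s[None, :] / T2[mono, None])
    nec = phantom.region_mask("necrotic")
    if nec.any():
        f = phantom.t2_short_fraction
        vol[nec] = S0[nec, None] * (
            f * np.exp(-te_s[None, :] / phantom.t2_short)
            + (1 - f) * np.exp(-te_s[None, :] / phantom.t2_long)
        )
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return vol
    return add_rician_noise(vol, sigma, rng)


# ---------------------------------------------------------------------------
# Monte-Carlo reflecting-sphere oracle


@njit(cache=True)
def _mc_walk(R, D, G, delta, Delta, gx, gy, gz, gamma, n_walkers, n_steps, seed):
    np.random.seed(seed)
    T = Delta + delta
    dt = T / n_steps
    sd = np.sqrt(2.0 * D * dt)
    cos_sum = 0.0
    cos2_sum = 0.0
    for w in range(n_walkers):
        # uniform start inside the sphere
        while True:
            x = (np.random.random() * 2 - 1) * R
            y = (np.random.random() * 2 - 1) * R
            z = (np.random.random() * 2 - 1) * R
            if x * x + y * y + z * z <= R * R:
                break
        phase = 0.0
        for s in range(n_steps):
            t = (s + 0.5) * dt
            if t < delta:
                geff = G
            elif t >= Delta and t < T:
                geff = -G
            else:
                geff = 0.0
            if geff != 0.0:
                phase += gamma * geff * (gx * x + gy * y + gz * z) * dt
            x += sd * np.random.normal()
            y += sd * np.random.normal()
            z += sd * np.random.normal()
            rr = np.sqrt(x * x + y * y + z * z)
            if rr > R:
                # mirror the overshoot back across the boundary radially
                scale = (2.0 * R - rr) / rr
                x *= scale
                y *= scale
                z *= scale
        c = np.cos(phase)
        cos_sum += c
        cos2_sum += c * c
    mean = cos_sum / n_walkers
    var = cos2_sum / n_walkers - mean * mean
    se = np.sqrt(var / n_walkers)
    return mean, se


def mc_sphere_oracle(
    R: float,
    D_I: float,
    meas: Measurement,
    n_walkers: int = 100_000,
    n_steps: Optional[int] = None,
    seed: int = 0,
):
    """Random-walk PGSE signal inside a reflecting sphere.

    ``R`` in um, ``D_I`` in um^2/ms.  Walkers take Gaussian steps of RMS
    length sqrt(6 D dt) and reflect elastically off the boundary; the
    phase accrues under the two rectangular gradient lobes.  Returns
    ``(attenuation, standard_error)``.
    """
    if n_walkers < 10_000:
        raise ValueError("need at least 1e4 walkers for a usable oracle")
    R_si = R * 1e-6
    D_si = D_I * 1e-9
    T = (meas.Delta + meas.delta) * 1e-3
    if n_steps is None:
        # choose dt so the RMS step is <= R/20
        dt = (R_si / 20.0) ** 2 / (6.0 * D_si)
        n_steps = max(200, int(np.ceil(T / dt)))
    step_len = np.sqrt(6.0 * D_si * T / n_steps)
    if step_len > R_si / 10.0:
        raise ValueError(
            f"step length {step_len:.2e} m exceeds R/10; increase n_steps"
        )
    gx, gy, gz = meas.direction
    mean, se = _mc_walk(
        R_si,
        D_si,
        meas.G * 1e-3,
        meas.delta * 1e-3,
        meas.Delta * 1e-3,
        gx,
        gy,
        gz,
        meas.gamma,
        n_walkers,
        int(n_steps),
        seed,
    )
    return abs(mean), se
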