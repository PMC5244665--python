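"""Voxel-wise maximum-likelihood model fitting under Rician noise.

Magnitude MR data are Rician distributed: the density of an observed
magnitude x given noiseless amplitude A and complex-channel noise SD
sigma is

    p(x | A, sigma) = x/sigma^2 exp(-(x^2 + A^2)/(2 sigma^2)) I0(x A / sigma^2)

The per-voxel fit maximises the corresponding log-likelihood over the
model's free parameters inside their box bounds, using a multi-start
local search: one start comes from a least-squares Ball / diffusion-
tensor cascade initialisation, the rest are drawn uniformly within
bounds from a seeded generator.  The noise SD is estimated from a
signal-free background region, whose magnitude data are Rayleigh
distributed with SD sigma*sqrt(2 - pi/2).

Averaged measurements (NEX > 1) are treated as Gaussian-equivalent with
their noise SD scaled by 1/sqrt(NEX); this is an approximation --
averaging magnitude images drives the statistics towards Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import i0e, i1e

from .compartments import (
    ModelSpec,
    ParamVector,
    PrecomputedScheme,
    get_model,
    frame_to_angles,
)
from .protocol import AcquisitionScheme

__all__ = [
    "NoiseEstimate",
    "FitResult",
    "estimate_noise_sigma",
    "rician_loglik",
    "expected_rician_mean",
    "fit_voxel",
    "fit_volume",
    "cascade_initialisation",
]

_RAYLEIGH_SD = np.sqrt(2.0 - np.pi / 2.0)


@dataclass
class NoiseEstimate:
    """Noise SD of the complex channels, with provenance."""

    sigma: float
    source: str = "background"

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    def per_measurement(self, scheme) -> np.ndarray:
        """Per-measurement SD, scaled by 1/sqrt(n_avg)."""
        n_avg = scheme.n_avg if hasattr(scheme, "n_avg") else np.asarray(scheme)
        return self.sigma / np.sqrt(n_avg.astype(float))


def estimate_noise_sigma(background_voxels, source: str = "background") -> NoiseEstimate:
    """Estimate sigma from magnitude samples of an empty (signal-free) region.

    Signal-free magnitude data follow a Rayleigh distribution whose SD is
    sigma*sqrt(2 - pi/2); the estimator inverts that relation.
    """
    x = np.asarray(background_voxels, dtype=float).ravel()
    if x.size < 50:
        raise ValueError(f"need at least 50 background samples, got {x.size}")
    if np.all(x == 0):
        raise ValueError("background region is identically zero")
    sd = float(np.std(x, ddof=1))
    return NoiseEstimate(sigma=sd / _RAYLEIGH_SD, source=source)


def _log_i0(z):
    # ln I0(z) = z + ln(i0e(z)), stable for large arguments
    return z + np.log(i0e(z))


def rician_loglik(observed, predicted, sigma) -> float:
    """Rician log-likelihood of observed magnitudes given predicted amplitudes.

    ``sigma`` may be scalar or per-measurement.  Non-positive observed
    values are excluded with a warning (magnitude data are positive).
    """
    x = np.asarray(observed, dtype=float)
    A = np.asarray(predicted, dtype=float)
    if x.shape != A.shape:
        raise ValueError("observed and predicted must have equal length")
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), x.shape)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    good = x > 0
    if not np.all(good):
        warnings.warn(
            f"excluding {int((~good).sum())} non-positive observations "
            "from the Rician likelihood",
            stacklevel=2,
        )
        x, A, sigma = x[good], A[good], sigma[good]
    s2 = sigma**2
    return float(
        np.sum(
            np.log(x) - 2.0 * np.log(sigma) - (x**2 + A**2) / (2.0 * s2)
            + _log_i0(x * A / s2)
        )
    )


def expected_rician_mean(predicted, sigma):
    """Expected magnitude E[x] for amplitude A and noise SD sigma.

    E[x] = sigma sqrt(pi/2) L_{1/2}(-A^2 / (2 sigma^2)), with L the
    Laguerre function; used to draw fitted curves over magnitude data.
    """
    A = np.asarray(predicted, dtype=float)
    if np.any(A < 0):
        raise ValueError("amplitude must be non-negative")
    x = A**2 / (2.0 * np.asarray(sigma, dtype=float) ** 2)
    # L_{1/2}(-x) = exp(-x/2) [(1+x) I0(x/2) + x I1(x/2)]
    lag = (1.0 + x) * i0e(x / 2.0) + x * i1e(x / 2.0)
    out = sigma * np.sqrt(np.pi / 2.0) * lag
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class FitResult:
    """Per-voxel maximum-likelihood estimate for one model."""

    model: str
    params: ParamVector
    x: np.ndarray
    lnL: float
    n: int
    converged: bool
    n_starts: int
    rng_seed: int


# ---------------------------------------------------------------------------
# initialisation cascade


def _loglinear_ball(data, cache):
    """LS fit of ln S = ln S0 - TE/T2 - b D; returns (S0, T2, D) clipped."""
    good = data > 0
    y = np.log(np.maximum(data[good], 1e-300))
    X = np.column_stack(
        [np.ones(good.sum()), -cache.TE_si[good], -cache.b_mm[good] * 1e-3]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    S0 = float(np.exp(np.clip(beta[0], -200, 200)))
    inv_T2 = max(beta[1], 1e-9)
    T2 = float(np.clip(1.0 / inv_T2, 0.0011, 2.99))
    D = float(np.clip(beta[2], 0.011, 2.99))
    return S0, T2, D


def _loglinear_tensor(data, cache):
    """LS diffusion-tensor fit; returns sorted eigenvalues and angles."""
    good = (data > 0) & (cache.b_mm > 0)
    if good.sum() < 10:
        return None
    y = np.log(np.maximum(data[good], 1e-300))
    g = cache.directions[good]
    b = cache.b_mm[good] * 1e-3
    X = np.column_stack(
        [
            np.ones(good.sum()),
            -cache.TE_si[good],
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    Dxx, Dyy, Dzz, Dxy, Dxz, Dyz = beta[2:]
    T = np.array([[Dxx, Dxy, Dxz], [Dxy, Dyy, Dyz], [Dxz, Dyz, Dzz]])
    evals, evecs = np.linalg.eigh(T)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.011, 2.99)
    evecs = evecs[:, order]
    theta, phi, alpha = frame_to_angles(evecs[:, 0], evecs[:, 1])
    return evals, (theta, phi, alpha)


def cascade_initialisation(data, cache) -> dict:
    """Ball + DT least-squares cascade used to seed the first start."""
    S0, T2, D = _loglinear_ball(data, cache)
    init = {
        "S0": S0,
        "T2": T2,
        "D1": D,
        "D2": max(0.011, 0.7 * D),
        "D3": max(0.011, 0.5 * D),
        "theta": np.pi / 4,
        "phi": np.pi / 4,
        "alpha": 0.1,
        "D_I": D,
        "R": 7.5,
        "f_I": 0.4,
    }
    dt = _loglinear_tensor(data, cache)
    if dt is not None:
        evals, (theta, phi, alpha) = dt
        init.update(
            D1=float(evals[0]),
            D2=float(evals[1]),
            D3=float(evals[2]),
            theta=float(np.clip(theta, 1e-3, np.pi - 1e-3)),
            phi=float(phi % (2 * np.pi)),
            alpha=float(np.clip(alpha, 1e-3, np.pi - 1e-3)),
            D_I=float(np.clip(np.mean(evals), 0.011, 2.99)),
        )
    return init


def _fit_bounds(spec: ModelSpec, data) -> list:
    """Box bounds with the open S0 interval replaced by a data-driven box."""
    dmax = float(np.max(data))
    out = []
    for name in spec.free_params:
        if name == "S0":
            out.append((1e-3 * dmax, 10.0 * dmax))
        else:
            out.append(spec.bounds[name])
    return out


def _random_start(spec, bounds, rng, init):
    x = np.empty(spec.k)
    for j, name in enumerate(spec.free_params):
        lo, hi = bounds[j]
        if name == "S0":
            x[j] = init["S0"] * rng.uniform(0.5, 2.0)
        elif name == "T2":
            x[j] = np.exp(rng.uniform(np.log(0.005), np.log(1.0)))
        else:
            x[j] = rng.uniform(lo, hi)
    # keep extracellular eigenvalues in canonical descending order
    dnames = [n for n in ("D1", "D2", "D3") if n in spec.free_params]
    if len(dnames) > 1:
        idx = [spec.free_params.index(n) for n in dnames]
        x[idx] = np.sort(x[idx])[::-1]
    xlo = np.array([b[0] for b in bounds])
    xhi = np.array([b[1] for b in bounds])
    return np.clip(x, xlo, xhi)


def _canonicalise(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Report Tensor fits with descending eigenvalues and angles in
    their fundamental domain (signal-invariant relabelling)."""
    names = spec.free_params
    x = x.copy()
    if "D3" in names:
        from .compartments import tensor_frame

        idx = [names.index(n) for n in ("D1", "D2", "D3")]
        evals = x[idx]
        order = np.argsort(evals)[::-1]
        if not np.array_equal(order, [0, 1, 2]):
            ia = [names.index(n) for n in ("theta", "phi", "alpha")]
            frame = tensor_frame(*x[ia])[order]
            theta, phi, alpha = frame_to_angles(frame[0], frame[1])
            x[idx] = evals[order]
            x[ia] = (theta, phi, alpha)
    for ang, period in (("phi", 2 * np.pi), ("alpha", np.pi)):
        if ang in names:
            x[names.index(ang)] %= period
    return x


def fit_voxel(
    data,
    scheme,
    spec,
    noise: NoiseEstimate,
    n_starts: int = 10,
    seed: int = 0,
    cache: Optional[PrecomputedScheme] = None,
) -> FitResult:
    """Maximum-likelihood fit of one model to one voxel's measurements.

    ``spec`` may be a ModelSpec or a registry name.  The search runs
    ``n_starts`` box-constrained local optimisations (L-BFGS-B): the
    first from the least-squares cascade initialisation, the remainder
    from uniform draws within bounds.  Never raises on optimiser
    failure; a fully failed search returns ``converged=False``.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    data = np.asarray(data, dtype=float).ravel()
    if cache is None:
        cache = PrecomputedScheme(scheme)
    if len(data) != cache.n:
        raise ValueError(
            f"data length {len(data)} does not match scheme length {cache.n}"
        )
    sigma_i = noise.per_measurement(cache)
    good = data > 0
    x_obs = data[good]
    sig_g = sigma_i[good]
    s2 = sig_g**2
    const = float(np.sum(np.log(x_obs) - 2.0 * np.log(sig_g) - x_obs**2 / (2 * s2)))

    from .compartments import predict_scheme  # local import to avoid cycle cost

    def negloglik(x):
        # const holds the A-independent likelihood terms
        A = predict_scheme(spec, x, cache)[good]
        return -(const + float(
            np.sum(-(A**2) / (2 * s2) + _log_i0(x_obs * A / s2))
        ))

    bounds = _fit_bounds(spec, data)
    rng = np.random.default_rng(seed)
    init = cascade_initialisation(data, cache)
    x0_first = np.array(
        [np.clip(init[name], *bounds[j]) for j, name in enumerate(spec.free_params)]
    )
    starts = [x0_first] + [
        _random_start(spec, bounds, rng, init) for _ in range(n_starts - 1)
    ]

    best_x, best_fun, converged = None, np.inf, False
    for x0 in starts:
        try:
            res = minimize(
                negloglik, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 400},
            )
        except FloatingPointError:  # pragma: no cover - defensive
            continue
        if np.isfinite(res.fun) and res.fun < best_fun:
            best_fun = float(res.fun)
            best_x = res.x.copy()
            converged = converged or bool(res.success)
    if best_x is None:
        best_x = x0_first
        best_fun = negloglik(x0_first)
        converged = False
    best_x = _canonicalise(spec, best_x)
    params = ParamVector.from_array(spec, best_x)
    return FitResult(
        model=spec.name,
        params=params,
        x=best_x,
        lnL=-best_fun,
        n=cache.n,
        converged=converged,
        n_starts=n_starts,
        rng_seed=seed,
    )


def fit_volume(
    data4d,
    scheme,
    spec,
    noise: NoiseEstimate,
    mask=None,
    n_starts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one model to every masked voxel of a 4-D volume.

    Returns a tidy DataFrame with voxel indices, fitted parameters, lnL
    and convergence flags; one row per voxel.  Each voxel's optimiser
    seed is derived deterministically from ``seed`` and its index.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    data4d = np.asarray(data4d, dtype=float)
    if mask is None:
        mask = np.ones(data4d.shape[:3], dtype=bool)
    cache = PrecomputedScheme(scheme)
    rows = []
    for count, (i, j, k) in enumerate(np.argwhere(mask)):
        fr = fit_voxel(
            data4d[i, j, k], scheme, spec, noise,
            n_starts=n_starts, seed=(seed + 7919 * count) % (2**31), cache=cache,
        )
        row = {"i": i, "j": j, "k": k, "model": fr.model, "lnL": fr.lnL,
               "k_params": spec.k, "n": fr.n, "converged": fr.converged}
        row.update({name: v for name, v in zip(spec.free_params, fr.x)})
        rows.append(row)
    return pd.DataFrame(rows)
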