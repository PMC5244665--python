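"""Analytic diffusion signal models for tissue compartments.

Four compartment shapes describe the normalised PGSE signal attenuation:

* **Ball** -- free isotropic diffusion, ``E = exp(-b D)``.
* **Zeppelin** -- cylindrically symmetric anisotropic free diffusion with
  axial/radial diffusivities ``D1 >= D2`` along an axis ``n(theta, phi)``:
  ``E = exp(-b [(D1 - D2)(g.n)^2 + D2])``.
* **Tensor** -- fully anisotropic free diffusion with eigenvalues
  ``D1 >= D2 >= D3``; the eigenframe is parameterised by the polar/azimuth
  angles (theta, phi) of the primary axis and a rotation ``alpha`` of the
  secondary axis about it.
* **Sphere** -- diffusion restricted inside an impermeable sphere of
  radius ``R``, evaluated with the Gaussian-phase-distribution (GPD,
  Murday-Cotts) series over the roots of the derivative of the
  first-order spherical Bessel function.

Composite tissue models combine an extracellular shape (Ball, Zeppelin or
Tensor) with an optional intracellular shape (Ball or Sphere) through
volume fractions ``f_E + f_I = 1``, and scale by the equilibrium signal
``S0`` and mono-exponential echo-time decay ``exp(-TE/T2)``:

    S = S0 exp(-TE/T2) (f_E E_extra + f_I E_intra)

The registry exposes the nine tested models by name (``"Ball"`` ...
``"Tensor-Sphere"``), each with its ordered free-parameter list, box
bounds and parameter count ``k``.

Unit conventions at this interface: diffusivities in um^2/ms
(numerically equal to 1e-3 mm^2/s), radii in um, T2 in s, b in s/mm^2,
angles in rad.  Internally everything is converted to SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .protocol import AcquisitionScheme, Measurement

__all__ = [
    "ParamVector",
    "ModelSpec",
    "MODELS",
    "get_model",
    "ball_signal",
    "zeppelin_signal",
    "tensor_signal",
    "sphere_signal",
    "composite_signal",
    "predict_scheme",
    "PrecomputedScheme",
    "sphere_gpd_attenuation",
    "bessel_derivative_roots",
    "GPDConvergenceError",
    "zeppelin_axis",
    "tensor_frame",
    "frame_to_angles",
]

# ---------------------------------------------------------------------------
# parameter container and model registry

_D_BOUNDS = (0.01, 3.0)      # um^2/ms, i.e. 1e-3 mm^2/s
_R_BOUNDS = (0.1, 20.0)      # um
_F_BOUNDS = (0.0, 1.0)
_T2_BOUNDS = (0.001, 3.0)    # s
_S0_BOUNDS = (0.0, np.inf)   # replaced by a data-driven box at fit time
_THETA_BOUNDS = (0.0, np.pi)
_PHI_BOUNDS = (0.0, 2.0 * np.pi)
_ALPHA_BOUNDS = (0.0, np.pi)

_BOUNDS = {
    "D1": _D_BOUNDS,
    "D2": _D_BOUNDS,
    "D3": _D_BOUNDS,
    "theta": _THETA_BOUNDS,
    "phi": _PHI_BOUNDS,
    "alpha": _ALPHA_BOUNDS,
    "D_I": _D_BOUNDS,
    "R": _R_BOUNDS,
    "f_I": _F_BOUNDS,
    "S0": _S0_BOUNDS,
    "T2": _T2_BOUNDS,
}


@dataclass
class ParamVector:
    """Named model parameters.

    Diffusivities (``D1 >= D2 >= D3``, ``D_I``) are in um^2/ms, ``R`` in
    um, ``T2`` in s, angles in rad; ``f_E`` is derived as ``1 - f_I``.
    Fields irrelevant to a given model are left ``None``.
    """

    D1: Optional[float] = None
    D2: Optional[float] = None
    D3: Optional[float] = None
    theta: Optional[float] = None
    phi: Optional[float] = None
    alpha: Optional[float] = None
    D_I: Optional[float] = None
    R: Optional[float] = None
    f_I: Optional[float] = None
    S0: float = 1.0
    T2: float = 0.1

    @property
    def f_E(self) -> Optional[float]:
        return None if self.f_I is None else 1.0 - self.f_I

    def to_array(self, spec: "ModelSpec") -> np.ndarray:
        vals = []
        for name in spec.free_params:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"parameter {name!r} required by {spec.name} is unset")
            vals.append(float(v))
        return np.array(vals)

    @classmethod
    def from_array(cls, spec: "ModelSpec", values) -> "ParamVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (spec.k,):
            raise ValueError(
                f"{spec.name} expects {spec.k} parameters, got {values.shape}"
            )
        return cls(**dict(zip(spec.free_params, values)))


@dataclass(frozen=True)
class ModelSpec:
    """A composite model: shapes, ordered free parameters and bounds."""

    name: str
    extracellular_shape: str
    intracellular_shape: Optional[str]
    free_params: tuple

    @property
    def k(self) -> int:
        """Number of free fitting parameters."""
        return len(self.free_params)

    @property
    def bounds(self) -> dict:
        return {p: _BOUNDS[p] for p in self.free_params}

    @property
    def two_compartment(self) -> bool:
        return self.intracellular_shape is not None

    def validate(self, params: ParamVector) -> None:
        """Raise ValueError naming the first out-of-bounds parameter."""
        for name in self.free_params:
            v = getattr(params, name)
            if v is None:
                raise ValueError(f"parameter {name!r} is unset for model {self.name}")
            lo, hi = _BOUNDS[name]
            if not (lo <= v <= hi):
                raise ValueError(
                    f"parameter {name!r}={v} outside bounds [{lo}, {hi}]"
                    f" for model {self.name}"
                )


_EC_PARAMS = {
    "Ball": ("D1",),
    "Zeppelin": ("D1", "D2", "theta", "phi"),
    "Tensor": ("D1", "D2", "D3", "theta", "phi", "alpha"),
}
_IC_PARAMS = {"Ball": ("D_I",), "Sphere": ("D_I", "R")}


def _make_spec(ec: str, ic: Optional[str]) -> ModelSpec:
    name = ec if ic is None else f"{ec}-{ic}"
    params = _EC_PARAMS[ec]
    if ic is not None:
        params = params + _IC_PARAMS[ic] + ("f_I",)
    params = params + ("S0", "T2")
    return ModelSpec(name, ec, ic, params)


#: The nine tested models, keyed by canonical name.
MODELS = {
    spec.name: spec
    for spec in (
        _make_spec(ec, ic)
        for ic in (None, "Ball", "Sphere")
        for ec in ("Ball", "Zeppelin", "Tensor")
    )
}


def _normalise_name(name: str) -> str:
    # accept en/em dashes, spaces and squashed ASCII aliases
    out = name.replace("–", "-").replace("—", "-").replace(" ", "")
    for canonical in MODELS:
        if out.replace("-", "").lower() == canonical.replace("-", "").lower():
            return canonical
    return out


def get_model(name: str) -> ModelSpec:
    """Look up a model by its registry name or an ASCII alias."""
    key = _normalise_name(name)
    try:
        return MODELS[key]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known models: {sorted(MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# orientation helpers


def zeppelin_axis(theta: float, phi: float) -> np.ndarray:
    """Unit vector with polar angle theta from +z and azimuth phi from +x."""
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def tensor_frame(theta: float, phi: float, alpha: float) -> np.ndarray:
    """Orthonormal eigenframe (rows e1, e2, e3) of the tensor model.

    e1 is the primary axis n(theta, phi); e2 is obtained by rotating the
    meridional unit vector by alpha about e1; e3 completes the frame.
    """
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    e1 = np.array([st * cp, st * sp, ct])
    e2_0 = np.array([ct * cp, ct * sp, -st])   # meridional (towards +z pole)
    e3_0 = np.array([-sp, cp, 0.0])            # azimuthal
    ca, sa = np.cos(alpha), np.sin(alpha)
    e2 = ca * e2_0 + sa * e3_0
    e3 = -sa * e2_0 + ca * e3_0
    return np.vstack([e1, e2, e3])


def frame_to_angles(e1: np.ndarray, e2: Optional[np.ndarray] = None):
    """Invert :func:`tensor_frame`: angles (theta, phi, alpha) of a frame.

    Antipodal equivalence is resolved by flipping e1 into the upper
    hemisphere (theta in [0, pi/2] preferred when e1_z < 0).
    """
    e1 = np.asarray(e1, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    if e1[2] < 0:
        e1 = -e1
        if e2 is not None:
            e2 = -np.asarray(e2, dtype=float)
    theta = float(np.arccos(np.clip(e1[2], -1, 1)))
    phi = float(np.arctan2(e1[1], e1[0])) % (2 * np.pi)
    if e2 is None:
        return theta, phi
    frame0 = tensor_frame(theta, phi, 0.0)
    alpha = float(np.arctan2(np.dot(e2, frame0[2]), np.dot(e2, frame0[1]))) % np.pi
    return theta, phi, alpha


# ---------------------------------------------------------------------------
# GPD (Murday-Cotts) restricted-sphere attenuation


class GPDConvergenceError(RuntimeError):
    """The GPD series did not converge within the allotted roots."""


def bessel_derivative_roots(n_roots: int = 40) -> np.ndarray:
    """First ``n_roots`` positive roots of d/dx j1(x) = 0.

    j1 is the first-order spherical Bessel function; its derivative
    vanishes where (x^2 - 2) sin x + 2 x cos x = 0.  The first root is
    ~2.0816; subsequent roots approach m*pi.
    """

    def f(x):
        return (x * x - 2.0) * np.sin(x) + 2.0 * x * np.cos(x)

    roots = []
    x = 1.0
    step = 0.05
    prev = f(x)
    while len(roots) < n_roots:
        x2 = x + step
        cur = f(x2)
        if prev == 0.0:
            roots.append(x)
        elif prev * cur < 0:
            roots.append(brentq(f, x, x2, xtol=1e-14, rtol=1e-15))
        x, prev = x2, cur
    return np.array(roots[:n_roots])


_GPD_ROOTS = bessel_derivative_roots(60)


def sphere_gpd_attenuation(
    G_si,
    delta_si,
    Delta_si,
    D_si: float,
    R_si: float,
    gamma: float,
    tol: float = 1e-8,
    roots: Optional[np.ndarray] = None,
) -> np.ndarray:
    """GPD series attenuation for restricted diffusion in a sphere (SI units).

    Broadcasts over measurement arrays ``G_si`` (T/m), ``delta_si`` and
    ``Delta_si`` (s); ``D_si`` in m^2/s, ``R_si`` in m.  Raises
    :class:`GPDConvergenceError` if the final retained term still moves
    ln E by more than ``tol``.
    """
    G_si = np.atleast_1d(np.asarray(G_si, dtype=float))
    delta_si = np.broadcast_to(np.asarray(delta_si, dtype=float), G_si.shape)
    Delta_si = np.broadcast_to(np.asarray(Delta_si, dtype=float), G_si.shape)
    if roots is None:
        roots = _GPD_ROOTS
    am = roots  # (M,)
    alpha = am / R_si                                    # (M,) 1/m
    a2D = (alpha**2) * D_si                              # (M,) 1/s
    # terms shape (n, M)
    ad = np.exp(-a2D[None, :] * delta_si[:, None])
    aD = np.exp(-a2D[None, :] * Delta_si[:, None])
    aDmd = np.exp(-a2D[None, :] * (Delta_si - delta_si)[:, None])
    aDpd = np.exp(-a2D[None, :] * (Delta_si + delta_si)[:, None])
    num = (
        2.0 * delta_si[:, None] * a2D[None, :]
        - 2.0
        + 2.0 * ad
        + 2.0 * aD
        - aDmd
        - aDpd
    )
    denom = (D_si**2) * (alpha**6) * (alpha**2 * R_si**2 - 2.0)
    terms = num / denom[None, :]
    ln_E = -2.0 * gamma**2 * G_si**2 * np.sum(terms, axis=1)
    tail = np.abs(2.0 * gamma**2 * G_si**2 * terms[:, -1])
    if np.any(tail > tol * np.maximum(np.abs(ln_E), 1.0)):
        raise GPDConvergenceError(
            f"GPD series not converged: last-term magnitude {tail.max():.3e} "
            f"exceeds tol={tol}; increase the number of roots"
        )
    return np.exp(ln_E)


# ---------------------------------------------------------------------------
# per-measurement signal functions (paper-style units)

_UM2_PER_MS_TO_SI = 1e-9   # um^2/ms -> m^2/s
_UM_TO_SI = 1e-6           # um -> m


def ball_signal(b, D: float):
    """Isotropic free-diffusion attenuation exp(-b D).

    ``b`` in s/mm^2, ``D`` in um^2/ms (= 1e-3 mm^2/s).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    out = np.exp(-b * D * 1e-3)
    return float(out) if out.ndim == 0 else out


def _check_direction(meas: Measurement) -> np.ndarray:
    g = np.asarray(meas.direction, dtype=float)
    if meas.G > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-9:
        raise ValueError("gradient direction must be a unit vector when G > 0")
    return g


def zeppelin_signal(meas: Measurement, D1: float, D2: float, theta: float, phi: float):
    """Cylindrically symmetric tensor attenuation (axial D1, radial D2)."""
    if D1 < D2:
        raise ValueError("zeppelin requires D1 >= D2")
    g = _check_direction(meas)
    n = zeppelin_axis(theta, phi)
    c2 = float(np.dot(g, n)) ** 2
    return float(np.exp(-meas.b * 1e-3 * ((D1 - D2) * c2 + D2)))


def tensor_signal(
    meas: Measurement,
    D1: float,
    D2: float,
    D3: float,
    theta: float,
    phi: float,
    alpha: float,
):
    """Full-tensor attenuation exp(-b g^T D g) with eigenvalues D1 >= D2 >= D3."""
    if not (D1 >= D2 >= D3):
        raise ValueError("tensor requires D1 >= D2 >= D3")
    g = _check_direction(meas)
    frame = tensor_frame(theta, phi, alpha)
    proj2 = (frame @ g) ** 2
    quad = D1 * proj2[0] + D2 * proj2[1] + D3 * proj2[2]
    return float(np.exp(-meas.b * 1e-3 * quad))


def sphere_signal(meas: Measurement, D_I: float, R: float):
    """Restricted-sphere attenuation (orientation independent), GPD series.

    ``D_I`` in um^2/ms, ``R`` in um.
    """
    if meas.G == 0:
        return 1.0
    out = sphere_gpd_attenuation(
        np.array([meas.G * 1e-3]),
        np.array([meas.delta * 1e-3]),
        np.array([meas.Delta * 1e-3]),
        D_I * _UM2_PER_MS_TO_SI,
        R * _UM_TO_SI,
        meas.gamma,
    )
    return float(out[0])


def composite_signal(spec: ModelSpec, params: ParamVector, meas: Measurement) -> float:
    """Full model signal S0 exp(-TE/T2) (f_E E_extra + f_I E_intra)."""
    spec.validate(params)
    ec = _extracellular_attenuation(spec, params, meas)
    decay = params.S0 * math.exp(-meas.TE * 1e-3 / params.T2)
    if not spec.two_compartment:
        return decay * ec
    ic = _intracellular_attenuation(spec, params, meas)
    return decay * ((1.0 - params.f_I) * ec + params.f_I * ic)


def _extracellular_attenuation(spec, params, meas):
    if spec.extracellular_shape == "Ball":
        return ball_signal(meas.b, params.D1)
    if spec.extracellular_shape == "Zeppelin":
        return zeppelin_signal(meas, params.D1, params.D2, params.theta, params.phi)
    return tensor_signal(
        meas, params.D1, params.D2, params.D3, params.theta, params.phi, params.alpha
    )


def _intracellular_attenuation(spec, params, meas):
    if spec.intracellular_shape == "Ball":
        return ball_signal(meas.b, params.D_I)
    return sphere_signal(meas, params.D_I, params.R)


# ---------------------------------------------------------------------------
# fast vectorised prediction over a whole scheme


class PrecomputedScheme:
    """Per-scheme arrays cached for fast repeated model evaluation.

    Groups measurements by unique (G, delta, Delta) so the GPD series is
    evaluated once per unique gradient combination rather than once per
    measurement/direction.
    """

    def __init__(self, scheme: AcquisitionScheme):
        self.scheme = scheme
        self.n = len(scheme)
        self.gamma = scheme.gamma
        self.b_mm = scheme.b                      # s/mm^2
        self.directions = scheme.directions
        self.TE_si = scheme.TE_si
        self.n_avg = scheme.n_avg
        key = np.stack([scheme.G_si, scheme.delta_si, scheme.Delta_si], axis=1)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        self.uniq_G = uniq[:, 0]
        self.uniq_delta = uniq[:, 1]
        self.uniq_Delta = uniq[:, 2]
        self.uniq_inverse = inv

    def sphere_attenuation(self, D_I: float, R: float) -> np.ndarray:
        """Per-measurement sphere attenuation; D_I in um^2/ms, R in um."""
        # looser truncation check on the optimiser hot path: a 1e-6
        # residual on ln E is far below noise and fit tolerances, and the
        # search must not raise while exploring parameter-space corners
        E_u = sphere_gpd_attenuation(
            self.uniq_G,
            self.uniq_delta,
            self.uniq_Delta,
            D_I * _UM2_PER_MS_TO_SI,
            R * _UM_TO_SI,
            self.gamma,
            tol=1e-6,
        )
        return E_u[self.uniq_inverse]


def predict_scheme(
    spec: ModelSpec,
    x: np.ndarray,
    cache: PrecomputedScheme,
    validate: bool = False,
) -> np.ndarray:
    """Predicted signal for every measurement of a scheme.

    ``x`` is the free-parameter vector in the order ``spec.free_params``.
    This is the hot path used by the fitting and MCMC loops.
    """
    p = dict(zip(spec.free_params, x))
    if validate:
        spec.validate(ParamVector(**p))
    b = cache.b_mm * 1e-3  # ms/um^2 so that b*D is dimensionless
    ec_shape = spec.extracellular_shape
    if ec_shape == "Ball":
        ec = np.exp(-b * p["D1"])
    elif ec_shape == "Zeppelin":
        n = zeppelin_axis(p["theta"], p["phi"])
        c2 = (cache.directions @ n) ** 2
        ec = np.exp(-b * ((p["D1"] - p["D2"]) * c2 + p["D2"]))
    else:
        frame = tensor_frame(p["theta"], p["phi"], p["alpha"])
        proj2 = (cache.directions @ frame.T) ** 2
        quad = proj2 @ np.array([p["D1"], p["D2"], p["D3"]])
        ec = np.exp(-b * quad)
    decay = p["S0"] * np.exp(-cache.TE_si / p["T2"])
    if not spec.two_compartment:
        return decay * ec
    if spec.intracellular_shape == "Ball":
        ic = np.exp(-b * p["D_I"])
    else:
        ic = cache.sphere_attenuation(p["D_I"], p["R"])
    f_I = p["f_I"]
    return decay * ((1.0 - f_I) * ec + f_I * ic)
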