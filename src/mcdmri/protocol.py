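"""Pulsed-gradient spin-echo (PGSE) acquisition schemes.

A scheme is an ordered list of measurements, each a pair of rectangular
diffusion-encoding gradient lobes of amplitude ``G``, duration ``delta``
and leading-edge separation ``Delta``, applied along a unit direction at
echo time ``TE``.  The diffusion weighting of such a measurement is the
Stejskal-Tanner b-value

    b = gamma^2 G^2 delta^2 (Delta - delta/3)

with ``gamma`` the gyromagnetic ratio of the spin species.

User-facing units follow the conventions of the imaging literature
(G in mT/m, times in ms, b in s/mm^2); all internal computation is done
in SI.  The module also builds the ex vivo breast study protocol: four
Delta/TE blocks (10/18, 30/45, 60/75, 80/95 ms) with gradient durations
of 3 or 10 ms and strengths up to 400 mT/m -- 42 distinct
(Delta, delta, G) combinations, each acquired along 3 directions with a
b = 0 image per block -- plus 42-direction DTI shells.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "Measurement",
    "AcquisitionScheme",
    "b_value",
    "build_study_protocol",
    "build_dti_shell",
    "build_full_protocol",
    "uniform_directions",
    "read_scheme",
    "write_scheme",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752218744e8

# Study protocol of the ex vivo breast acquisition: per Delta/TE block,
# the gradient duration(s) and the gradient strengths (mT/m) with their
# NEX (number of averages, 1 unless noted).
_STUDY_BLOCKS = [
    # (Delta ms, TE ms, delta ms, [(G mT/m, NEX), ...])
    (10.0, 18.0, 3.0, [(g, 1) for g in range(40, 401, 40)]),
    (30.0, 45.0, 3.0, [(40, 1), (80, 1), (120, 1), (160, 1), (200, 4), (240, 8)]),
    (30.0, 45.0, 10.0, [(40, 1), (80, 1), (120, 1), (160, 1), (200, 4), (240, 8)]),
    (60.0, 75.0, 3.0, [(40, 1), (80, 1), (120, 1), (160, 2), (200, 8)]),
    (60.0, 75.0, 10.0, [(40, 1), (80, 1), (120, 1), (160, 2), (200, 8)]),
    (80.0, 95.0, 3.0, [(40, 1), (80, 1), (120, 2), (160, 4), (200, 10)]),
    (80.0, 95.0, 10.0, [(40, 1), (80, 1), (120, 2), (160, 4), (200, 10)]),
]


def b_value(G, delta, Delta, gamma=GAMMA_PROTON):
    """Stejskal-Tanner b-value for rectangular gradient lobes.

    Parameters
    ----------
    G : float or array
        Gradient amplitude in mT/m.
    delta, Delta : float or array
        Gradient duration and separation in ms; requires 0 < delta < Delta.
    gamma : float
        Gyromagnetic ratio in rad s^-1 T^-1.

    Returns
    -------
    b : float or array
        Diffusion weighting in s/mm^2.
    """
    G = np.asarray(G, dtype=float)
    delta = np.asarray(delta, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    if np.any(G < 0):
        raise ValueError("gradient amplitude G must be non-negative")
    if np.any(delta <= 0) or np.any(Delta <= 0):
        raise ValueError("gradient timings delta, Delta must be positive")
    if np.any(delta >= Delta):
        raise ValueError("require delta < Delta for the Stejskal-Tanner form")
    G_si = G * 1e-3          # T/m
    d_si = delta * 1e-3      # s
    D_si = Delta * 1e-3      # s
    b_si = gamma**2 * G_si**2 * d_si**2 * (D_si - d_si / 3.0)  # s/m^2
    out = b_si / 1e6         # s/mm^2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Measurement:
    """One PGSE measurement in conventional imaging units (mT/m, ms)."""

    direction: tuple
    G: float
    delta: float
    Delta: float
    TE: float
    n_avg: int = 1
    gamma: float = GAMMA_PROTON

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError("direction must be a 3-vector")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.G > 0 and abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector when G > 0")
        if not (0 < self.delta < self.Delta <= self.TE):
            raise ValueError("require 0 < delta < Delta <= TE")
        if self.n_avg < 1:
            raise ValueError("n_avg must be >= 1")
        object.__setattr__(self, "direction", tuple(float(x) for x in d))

    @property
    def b(self) -> float:
        """b-value in s/mm^2 (0 iff G = 0)."""
        if self.G == 0:
            return 0.0
        return b_value(self.G, self.delta, self.Delta, self.gamma)


class AcquisitionScheme:
    """An ordered set of PGSE measurements with vectorised SI views.

    Attributes exposed for model code (all numpy arrays of length n):
    ``directions`` (n, 3) unit vectors (arbitrary for b=0 rows),
    ``G_si`` (T/m), ``delta_si``/``Delta_si``/``TE_si`` (s), ``n_avg``,
    ``b`` (s/mm^2).
    """

    def __init__(self, measurements, gamma: float = GAMMA_PROTON):
        meas = list(measurements)
        if not meas:
            raise ValueError("scheme must contain at least one measurement")
        self.measurements = [replace(m, gamma=gamma) for m in meas]
        self.gamma = float(gamma)
        self.directions = np.array([m.direction for m in self.measurements])
        self.G_si = np.array([m.G for m in self.measurements]) * 1e-3
        self.delta_si = np.array([m.delta for m in self.measurements]) * 1e-3
        self.Delta_si = np.array([m.Delta for m in self.measurements]) * 1e-3
        self.TE_si = np.array([m.TE for m in self.measurements]) * 1e-3
        self.n_avg = np.array([m.n_avg for m in self.measurements], dtype=int)
        self.b = np.array([m.b for m in self.measurements])

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return (
            len(self) == len(other)
            and math.isclose(self.gamma, other.gamma, rel_tol=1e-12)
            and self.measurements == other.measurements
        )

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.G_si == 0))

    def validate(self) -> None:
        """Check the scheme-level invariants (at least one b=0 image)."""
        if self.n_b0 == 0:
            raise ValueError("scheme must contain at least one b = 0 measurement")

    def concatenated(self, other: "AcquisitionScheme") -> "AcquisitionScheme":
        return AcquisitionScheme(
            self.measurements + other.measurements, gamma=self.gamma
        )


_DEFAULT_DIRECTIONS = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
)


def build_study_protocol(
    directions=_DEFAULT_DIRECTIONS,
    gamma: float = GAMMA_PROTON,
    n_b0_per_block: int = 1,
) -> AcquisitionScheme:
    """Build the 42-combination DWI protocol.

    Each of the 42 (Delta, delta, G) combinations is acquired along each
    of the given three directions; every Delta/TE block additionally
    carries ``n_b0_per_block`` unweighted (b = 0) measurements.  NEX
    follows the acquisition table (high-G measurements were averaged).
    """
    dirs = [np.asarray(d, dtype=float) for d in directions]
    if len(dirs) != 3:
        raise ValueError("expected three gradient directions")
    for i, d in enumerate(dirs):
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError(f"direction {i} is not a unit vector")
    for i in range(3):
        for j in range(i + 1, 3):
            if np.allclose(dirs[i], dirs[j]):
                raise ValueError("directions must be mutually distinct")

    meas = []
    seen_blocks = set()
    for Delta, TE, delta, strengths in _STUDY_BLOCKS:
        block = (Delta, TE)
        if block not in seen_blocks:
            seen_blocks.add(block)
            for _ in range(n_b0_per_block):
                meas.append(
                    Measurement((1.0, 0.0, 0.0), 0.0, delta, Delta, TE, 1, gamma)
                )
        for G, nex in strengths:
            for d in dirs:
                meas.append(Measurement(tuple(d), float(G), delta, Delta, TE, nex, gamma))
    scheme = AcquisitionScheme(meas, gamma=gamma)
    scheme.validate()
    return scheme


def uniform_directions(n: int, seed: int = 0, n_iter: int = 2000) -> np.ndarray:
    """Approximately uniform unit vectors by electrostatic repulsion.

    Minimises the antipodally symmetric Coulomb energy
    sum_{i<j} 1/|x_i - x_j|^2 + 1/|x_i + x_j|^2 by projected gradient
    descent from a seeded random start.  Returns an (n, 3) array.
    """
    if n < 1:
        raise ValueError("n must be positive")
    # deterministic golden-spiral start on the upper hemisphere
    i = np.arange(n)
    z = (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden + 0.1 * seed
    x = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    if n == 1:
        return x
    eye = np.eye(n, dtype=bool)
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        summ = x[:, None, :] + x[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        s2 = np.sum(summ**2, axis=-1)
        d2[eye] = np.inf
        s2[eye] = np.inf
        f = np.sum(2 * diff / d2[..., None] ** 2, axis=1)
        f += np.sum(2 * summ / s2[..., None] ** 2, axis=1)
        # project onto tangent plane and cap the displacement per sweep
        f -= np.sum(f * x, axis=1, keepdims=True) * x
        fmax = np.max(np.linalg.norm(f, axis=1))
        if fmax == 0:
            break
        x = x + (0.02 / fmax) * f
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def build_dti_shell(
    n_dirs: int,
    G: float,
    delta: float = 4.5,
    Delta: float = 20.0,
    TE: float = 30.0,
    n_b0: int = 6,
    gamma: float = GAMMA_PROTON,
    seed: int = 0,
) -> AcquisitionScheme:
    """A single-shell DTI acquisition: n_dirs uniform directions + b=0 images.

    Defaults reproduce the study's DTI scans (delta = 4.5 ms, Delta = 20 ms,
    TE = 30 ms, 42 directions + six unweighted images).
    """
    if n_dirs < 6:
        raise ValueError("a DTI shell needs at least 6 directions")
    if G < 0:
        raise ValueError("G must be non-negative")
    dirs = uniform_directions(n_dirs, seed=seed)
    meas = [
        Measurement((1.0, 0.0, 0.0), 0.0, delta, Delta, TE, 1, gamma)
        for _ in range(n_b0)
    ]
    meas += [Measurement(tuple(d), float(G), delta, Delta, TE, 1, gamma) for d in dirs]
    scheme = AcquisitionScheme(meas, gamma=gamma)
    scheme.validate()
    return scheme


def build_full_protocol(
    directions=_DEFAULT_DIRECTIONS,
    dti_strengths=(187.0, 226.0),
    gamma: float = GAMMA_PROTON,
    seed: int = 0,
) -> AcquisitionScheme:
    """The DWI study protocol concatenated with the two 42-direction DTI shells."""
    scheme = build_study_protocol(directions, gamma=gamma)
    for G in dti_strengths:
        scheme = scheme.concatenated(build_dti_shell(42, G, gamma=gamma, seed=seed))
    return scheme


_UNIT_SCALES = {"mT/m": 1.0, "T/m": 1e3, "ms": 1.0, "s": 1e3}


def write_scheme(scheme: AcquisitionScheme, path) -> None:
    """Write a scheme as whitespace-delimited text.

    Columns: gx gy gz |G| delta Delta TE n_avg, in mT/m and ms; a header
    line declares the units and the gyromagnetic ratio.
    """
    lines = [
        "# PGSE acquisition scheme",
        f"# gamma = {scheme.gamma!r} rad/s/T",
        "# units: G=mT/m time=ms",
        "# gx gy gz G delta Delta TE n_avg",
    ]
    for m in scheme.measurements:
        gx, gy, gz = m.direction
        lines.append(
            f"{gx!r} {gy!r} {gz!r} {m.G!r} {m.delta!r} {m.Delta!r} {m.TE!r} {m.n_avg}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


class SchemeParseError(ValueError):
    """Malformed scheme file; message names the offending line."""


def read_scheme(path) -> AcquisitionScheme:
    """Read a scheme written by :func:`write_scheme` (or hand-edited)."""
    if hasattr(path, "read"):
        fh = io.StringIO(path.read())
    else:
        fh = open(path)
    gamma = GAMMA_PROTON
    g_scale = 1.0
    t_scale = 1.0
    meas = []
    with fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("gamma"):
                    try:
                        gamma = float(body.split("=")[1].split()[0])
                    except (IndexError, ValueError) as exc:
                        raise SchemeParseError(
                            f"line {lineno}: cannot parse gamma: {line!r}"
                        ) from exc
                elif body.startswith("units:"):
                    for tok in body[len("units:"):].split():
                        key, _, val = tok.partition("=")
                        if val not in _UNIT_SCALES:
                            raise SchemeParseError(
                                f"line {lineno}: unknown unit {val!r}"
                            )
                        if key == "G":
                            g_scale = _UNIT_SCALES[val]
                        elif key == "time":
                            t_scale = _UNIT_SCALES[val]
                continue
            parts = line.split()
            if len(parts) not in (7, 8):
                raise SchemeParseError(
                    f"line {lineno}: expected 7 or 8 columns, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts[:7]]
                nex = int(parts[7]) if len(parts) == 8 else 1
            except ValueError as exc:
                raise SchemeParseError(
                    f"line {lineno}: non-numeric field in {line!r}"
                ) from exc
            gx, gy, gz, G, delta, Delta, TE = vals
            try:
                meas.append(
                    Measurement(
                        (gx, gy, gz),
                        G * g_scale,
                        delta * t_scale,
                        Delta * t_scale,
                        TE * t_scale,
                        nex,
                        gamma,
                    )
                )
            except ValueError as exc:
                raise SchemeParseError(f"line {lineno}: {exc}") from exc
    if not meas:
        raise SchemeParseError("scheme file contains no measurements")
    return AcquisitionScheme(meas, gamma=gamma)
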