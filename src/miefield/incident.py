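"""Focused incident field of an annular condenser.

The scalar focused field is the closed-form partial-wave series

    E_f(p) = 2 pi E0 sum_l i^l j_l(k r) P_l(cos theta) c_l

with r = |p - p_f|, theta measured from the optical axis (+z) at the focal
point, and c_l the annular-aperture coefficients.  Because only (r, theta)
enter, the field is circularly symmetric about the axis and can be cached
in a quarter-plane lookup table (axial coordinate u >= 0, radial v >= 0);
the mirrored axial side is recovered by complex conjugation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .sphmath import aperture_coeffs, legendre_sequence, max_order, spherical_jn_all

logger = logging.getLogger(__name__)

__all__ = [
    "FieldSlice",
    "IncidentLUT",
    "OpticalConfig",
    "focused_field",
    "incident_lut",
    "plane_wave",
    "required_order",
    "sample_incident_lut",
]

_AXIS = np.array([0.0, 0.0, 1.0])  # optical axis, light propagating toward +z


def required_order(k: float, r_max: float) -> int:
    """Truncation order for series convergence out to radius ``r_max``."""
    x = max(k * r_max, 1e-6)
    return int(np.ceil(x + 4.0 * np.cbrt(x) + 2.0))


@dataclass
class OpticalConfig:
    """Condenser illumination settings at a single wavelength.

    ``alpha1 < alpha2`` are the polar angles of the annular aperture
    (``alpha = arcsin(NA)``); ``order=None`` selects the convergence order
    adaptively from the evaluation radius at call time.
    """

    lam: float
    alpha1: float
    alpha2: float
    E0: complex = 1.0 + 0.0j
    p_f: np.ndarray = field(default_factory=lambda: np.zeros(3))
    order: int | None = None

    def __post_init__(self) -> None:
        self.p_f = np.asarray(self.p_f, dtype=float).reshape(3)
        self.E0 = complex(self.E0)
        if self.lam <= 0:
            raise ValidationError("wavelength must be > 0")
        if not (0.0 <= self.alpha1 < self.alpha2 <= np.pi / 2 + 1e-12):
            raise ValidationError(
                f"require 0 <= alpha1 < alpha2 <= pi/2, got ({self.alpha1}, {self.alpha2})"
            )
        if self.order is not None and self.order < 1:
            raise ValidationError("order must be >= 1")

    @property
    def k(self) -> float:
        """Wavenumber 2 pi / lam in rad/um."""
        return 2.0 * np.pi / self.lam

    @classmethod
    def from_na(cls, lam: float, na_in: float, na_out: float, **kwargs) -> "OpticalConfig":
        """Build from an (inner, outer) NA pair via alpha = arcsin(NA)."""
        if not (0.0 <= na_in < na_out <= 1.0):
            raise ValidationError(f"require 0 <= NA_in < NA_out <= 1, got ({na_in}, {na_out})")
        return cls(lam=lam, alpha1=float(np.arcsin(na_in)),
                   alpha2=float(np.arcsin(na_out)), **kwargs)

    def with_wavelength(self, lam: float) -> "OpticalConfig":
        return replace(self, lam=lam)

    def with_focus(self, p_f) -> "OpticalConfig":
        return replace(self, p_f=np.asarray(p_f, dtype=float))


@dataclass
class FieldSlice:
    """Square planar grid of complex field samples.

    Sample (i, j) sits at ``origin + ((i+0.5)/R - 0.5) S u + ((j+0.5)/R - 0.5) S v``.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    extent: float
    resolution: int
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axis_u = np.asarray(self.axis_u, dtype=float).reshape(3)
        self.axis_v = np.asarray(self.axis_v, dtype=float).reshape(3)
        if self.resolution < 2:
            raise ValidationError("slice resolution must be >= 2")
        if self.extent <= 0:
            raise ValidationError("slice extent must be > 0")
        for name, ax in (("axis_u", self.axis_u), ("axis_v", self.axis_v)):
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be unit length")
        if abs(self.axis_u @ self.axis_v) > 1e-9:
            raise ValidationError("axis_u and axis_v must be orthogonal")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=complex)
            if self.samples.shape != (self.resolution, self.resolution):
                raise ValidationError("samples must be (R, R)")

    def grid_points(self) -> np.ndarray:
        """All sample positions, shape (R*R, 3), row-major in (i, j)."""
        R, S = self.resolution, self.extent
        t = ((np.arange(R) + 0.5) / R - 0.5) * S
        return (self.origin[None, None, :]
                + t[:, None, None] * self.axis_u[None, None, :]
                + t[None, :, None] * self.axis_v[None, None, :]).reshape(-1, 3)

    def with_samples(self, samples) -> "FieldSlice":
        return FieldSlice(self.origin, self.axis_u, self.axis_v,
                          self.extent, self.resolution,
                          np.asarray(samples, dtype=complex).reshape(
                              self.resolution, self.resolution))


def plane_wave(config: OpticalConfig, direction, points) -> np.ndarray:
    """E0 * exp(i k d . r) at each point (unit propagation direction d)."""
    d = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(d)
    if abs(norm - 1.0) > 1e-9:
        logger.warning("plane_wave: direction not unit length (|d|=%.6g); normalizing", norm)
        d = d / norm
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return config.E0 * np.exp(1j * config.k * (pts @ d))


def _series_order(config: OpticalConfig, r_max: float) -> int:
    need = required_order(config.k, r_max)
    if config.order is None:
        return need
    if config.order < need:
        logger.warning("focused_field: order %d below the convergence "
                       "requirement %d for radius %.3g um; series truncated",
                       config.order, need, r_max)
    return config.order


def focused_field(config: OpticalConfig, points, chunk: int = 16384) -> np.ndarray:
    """Closed-form focused field at the given points (shape (N,) complex)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - config.p_f[None, :]
    r = np.linalg.norm(rel, axis=1)
    L = _series_order(config, float(r.max(initial=0.0)))
    c = aperture_coeffs(L, config.alpha1, config.alpha2)
    il = 1j ** np.arange(L + 1)
    w = (il * c).astype(complex)
    k = config.k
    out = np.empty(pts.shape[0], dtype=complex)
    for s in range(0, pts.shape[0], chunk):
        rr = r[s:s + chunk]
        with np.errstate(invalid="ignore"):
            ct = np.where(rr > 0, rel[s:s + chunk, 2] / np.where(rr > 0, rr, 1.0), 1.0)
        ct = np.clip(ct, -1.0, 1.0)
        j = spherical_jn_all(L, k * rr)              # (L+1, n)
        P = legendre_sequence(L, ct)                 # (L+1, n)
        out[s:s + chunk] = w @ (j * P)
    return 2.0 * np.pi * config.E0 * out


@dataclass
class IncidentLUT:
    """Quarter-plane cache of the focused field in cylindrical coordinates.

    ``values[i, j]`` holds E_f at axial offset ``u_axis[i] >= 0`` and radial
    offset ``v_axis[j] >= 0`` from the focal point.  The mirrored axial side
    (u < 0) is E0 * conj(E/E0); radial symmetry covers all azimuths.
    """

    u_axis: np.ndarray
    v_axis: np.ndarray
    values: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.u_axis = np.asarray(self.u_axis, dtype=float)
        self.v_axis = np.asarray(self.v_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (self.u_axis.size, self.v_axis.size):
            raise ValidationError("LUT values shape must be (len(u_axis), len(v_axis))")


def incident_lut(config: OpticalConfig, u_range: float, v_range: float,
                 resolution: int) -> IncidentLUT:
    """Tabulate the focused field on the quarter plane [0,u_range]x[0,v_range]."""
    if u_range <= 0 or v_range <= 0:
        raise ValidationError("u_range and v_range must be > 0")
    u = np.linspace(0.0, u_range, resolution)
    v = np.linspace(0.0, v_range, resolution)
    U, V = np.meshgrid(u, v, indexing="ij")
    pts = (config.p_f[None, :]
           + U.reshape(-1, 1) * _AXIS[None, :]
           + V.reshape(-1, 1) * np.array([1.0, 0.0, 0.0])[None, :])
    vals = focused_field(config, pts).reshape(resolution, resolution)
    return IncidentLUT(u, v, vals, config)


def sample_incident_lut(lut: IncidentLUT, points) -> np.ndarray:
    """Bilinear LUT lookup; mirrored axial side returned as the conjugate."""
    cfg = lut.config
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - cfg.p_f[None, :]
    u = rel[:, 2]
    v = np.hypot(rel[:, 0], rel[:, 1])
    au = np.abs(u)
    if np.any(au > lut.u_axis[-1] + 1e-12) or np.any(v > lut.v_axis[-1] + 1e-12):
        logger.warning("sample_incident_lut: query outside table range; clamping")
    vals = _bilinear(lut.u_axis, lut.v_axis, lut.values, au, v)
    mirror = u < 0
    if np.any(mirror):
        # conjugation applies to the field normalized by E0
        vals[mirror] = cfg.E0 * np.conj(vals[mirror] / cfg.E0)
    return vals


def _bilinear(xa: np.ndarray, ya: np.ndarray, table: np.ndarray,
              x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x = np.clip(x, xa[0], xa[-1])
    y = np.clip(y, ya[0], ya[-1])
    i = np.clip(np.searchsorted(xa, x) - 1, 0, xa.size - 2)
    j = np.clip(np.searchsorted(ya, y) - 1, 0, ya.size - 2)
    tx = (x - xa[i]) / (xa[i + 1] - xa[i])
    ty = (y - ya[j]) / (ya[j + 1] - ya[j])
    return ((1 - tx) * (1 - ty) * table[i, j]
            + tx * (1 - ty) * table[i + 1, j]
            + (1 - tx) * ty * table[i, j + 1]
            + tx * ty * table[i + 1, j + 1])
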