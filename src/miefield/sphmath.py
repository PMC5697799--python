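"""Special-function kernel: spherical Bessel/Hankel families, Legendre
recursions, annular-aperture coefficients and the series convergence order.

All field series in this package are built from three ingredients computed
here:

* spherical Bessel functions ``j_l``, ``y_l`` and the outgoing Hankel
  function ``h1_l = j_l + i y_l`` together with their derivatives
  (time convention ``e^{-i omega t}``, so ``h1_l`` is the outgoing wave);
* Legendre polynomials ``P_l`` evaluated by the stable three-term
  recurrence;
* per-order aperture coefficients ``c_l`` for an annular condenser
  subtending polar angles ``[alpha1, alpha2]``.

Real arguments are delegated to :func:`scipy.special.spherical_jn` /
``spherical_yn``; complex arguments (needed for fields inside absorbing
spheres) use the half-integer cylindrical Bessel functions from the Amos
library via :func:`scipy.special.jv` / ``yv``.  Derivatives are obtained
from the exact recurrence ``f'_l = f_{l-1} - ((l+1)/z) f_l`` rather than
finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import special as _sp

from .exceptions import DomainError, SingularityError, ValidationError

__all__ = [
    "BesselFamily",
    "OrderTable",
    "aperture_coeffs",
    "legendre_sequence",
    "max_order",
    "spherical_bessel_family",
    "spherical_jn_all",
]


def max_order(a: float, lam: float) -> int:
    """Series order required for convergence of a size-parameter x sphere.

    ``N_l = ceil(x + 4 x^(1/3) + 2)`` with ``x = 2 pi a / lam`` (the
    Bohren–Huffman truncation rule).

    Parameters
    ----------
    a : float
        Sphere radius (or evaluation radius) in micrometres, > 0.
    lam : float
        Wavelength in micrometres, > 0.
    """
    if a <= 0 or lam <= 0:
        raise ValidationError(f"max_order requires a > 0 and lam > 0, got a={a}, lam={lam}")
    x = 2.0 * np.pi * a / lam
    return int(np.ceil(x + 4.0 * np.cbrt(x) + 2.0))


def legendre_sequence(l_max: int, x) -> np.ndarray:
    """Legendre polynomials ``P_0..P_{l_max}`` at ``x`` in [-1, 1].

    Uses the three-term recurrence ``l P_l = (2l-1) x P_{l-1} - (l-1) P_{l-2}``,
    exact at the endpoints.  Returns an array of shape ``(l_max+1,) + x.shape``.
    """
    if l_max < 0:
        raise ValidationError("l_max must be >= 0")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise DomainError("legendre_sequence requires |x| <= 1")
    x = np.clip(x, -1.0, 1.0)
    out = np.empty((l_max + 1,) + x.shape, dtype=float)
    out[0] = 1.0
    if l_max >= 1:
        out[1] = x
    for l in range(2, l_max + 1):
        out[l] = ((2 * l - 1) * x * out[l - 1] - (l - 1) * out[l - 2]) / l
    return out


class BesselFamily(NamedTuple):
    """Spherical Bessel/Hankel values and derivatives for l = 0..l_max.

    Each member has shape ``(l_max+1,) + z.shape``.
    """

    j: np.ndarray
    y: np.ndarray
    h1: np.ndarray
    dj: np.ndarray
    dy: np.ndarray
    dh1: np.ndarray


def _derivative_from_recurrence(f: np.ndarray, z: np.ndarray) -> np.ndarray:
    """f'_l = f_{l-1} - ((l+1)/z) f_l; f is computed to one extra order."""
    l_max = f.shape[0] - 2
    df = np.empty((l_max + 1,) + f.shape[1:], dtype=f.dtype)
    df[0] = -f[1]
    for l in range(1, l_max + 1):
        df[l] = f[l - 1] - (l + 1) / z * f[l]
    return df


def spherical_jn_all(l_max: int, z, derivative: bool = False):
    """``j_l(z)`` for l = 0..l_max, real or complex argument, z = 0 allowed.

    Complex arguments are evaluated as ``sqrt(pi/(2z)) J_{l+1/2}(z)``;
    ``j_l(0)`` is the series limit (1 for l = 0, else 0).  With
    ``derivative=True`` returns ``(j, dj)`` where ``dj`` comes from the
    downward derivative recurrence (``dj_1(0) = 1/3`` handled explicitly).
    """
    if l_max < 0:
        raise ValidationError("l_max must be >= 0")
    z_arr = np.asarray(z)
    scalar = z_arr.ndim == 0
    z_arr = np.atleast_1d(z_arr)
    L = l_max + 1  # extra order for the derivative recurrence
    orders = np.arange(L + 1)
    if np.iscomplexobj(z_arr):
        zero = z_arr == 0
        zsafe = np.where(zero, 1.0, z_arr)
        with np.errstate(invalid="ignore", over="ignore"):
            j = np.sqrt(np.pi / (2.0 * zsafe)) * _sp.jv(orders[:, None] + 0.5, zsafe[None, :])
        if np.any(zero):
            j[:, zero] = 0.0
            j[0, zero] = 1.0
    else:
        z_arr = z_arr.astype(float)
        j = _sp.spherical_jn(orders[:, None], z_arr[None, :])
    if not derivative:
        out = j[: l_max + 1]
        return out[:, 0] if scalar else out
    zero = z_arr == 0
    zsafe = np.where(zero, 1.0, z_arr)
    dj = _derivative_from_recurrence(j, zsafe)
    if np.any(zero):
        dj[:, zero] = 0.0
        if l_max >= 1:
            dj[1, zero] = 1.0 / 3.0
    j = j[: l_max + 1]
    if scalar:
        return j[:, 0], dj[:, 0]
    return j, dj


def spherical_bessel_family(l_max: int, z) -> BesselFamily:
    """All six families j, y, h1 and derivatives for l = 0..l_max.

    ``z`` may be real (any nonzero value) or complex with nonzero modulus.
    ``y_l`` overflow for large l at tiny |z| saturates to ``+/-inf``, which is
    the documented overflow flag.
    """
    if l_max < 0:
        raise ValidationError("l_max must be >= 0")
    z_arr = np.asarray(z)
    scalar = z_arr.ndim == 0
    z_arr = np.atleast_1d(z_arr)
    if np.any(z_arr == 0):
        raise SingularityError("y_l / h1_l are singular at z = 0")
    orders = np.arange(l_max + 2)
    if np.iscomplexobj(z_arr):
        factor = np.sqrt(np.pi / (2.0 * z_arr))[None, :]
        nu = orders[:, None] + 0.5
        with np.errstate(invalid="ignore", over="ignore"):
            j = factor * _sp.jv(nu, z_arr[None, :])
            y = factor * _sp.yv(nu, z_arr[None, :])
    else:
        z_f = z_arr.astype(float)
        j = _sp.spherical_jn(orders[:, None], z_f[None, :])
        with np.errstate(over="ignore"):
            y = _sp.spherical_yn(orders[:, None], z_f[None, :])
    dj = _derivative_from_recurrence(j, z_arr)
    dy = _derivative_from_recurrence(y, z_arr)
    j, y = j[: l_max + 1], y[: l_max + 1]
    h1 = j + 1j * y
    dh1 = dj + 1j * dy
    fam = BesselFamily(j, y, h1, dj, dy, dh1)
    if scalar:
        fam = BesselFamily(*(m[:, 0] for m in fam))
    return fam


def aperture_coeffs(l_max: int, alpha1: float, alpha2: float) -> np.ndarray:
    """Annular-aperture coefficients c_l for polar angles [alpha1, alpha2].

    ``c_l = P_{l+1}(cos a1) - P_{l+1}(cos a2) - P_{l-1}(cos a1) + P_{l-1}(cos a2)``
    with the convention ``P_{-1} = 1``, which makes ``c_l`` equal
    ``(2l+1) * integral_{a1}^{a2} P_l(cos t) sin t dt`` (so ``c_0 =
    cos alpha1 - cos alpha2``).
    """
    if not (0.0 <= alpha1 < alpha2 <= np.pi):
        raise ValidationError(
            f"require 0 <= alpha1 < alpha2 <= pi, got alpha1={alpha1}, alpha2={alpha2}"
        )
    x = np.array([np.cos(alpha1), np.cos(alpha2)])
    P = legendre_sequence(l_max + 1, x)  # (l_max+2, 2)
    # prepend P_{-1} = 1
    Pm = np.vstack([np.ones((1, 2)), P])  # row index l+1 holds P_l
    l = np.arange(l_max + 1)
    c = (Pm[l + 2, 0] - Pm[l + 2, 1]) - (Pm[l, 0] - Pm[l, 1])
    return c


@dataclass
class OrderTable:
    """Per-order radial lookup table: rows are orders l, columns abscissa.

    A cheap software analogue of the texture caches used to accelerate
    repeated radial special-function evaluation.  Linear interpolation
    between samples, clamped at the ends.
    """

    abscissa: np.ndarray
    values: np.ndarray  # (l_max+1, R) complex

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.values = np.asarray(self.values)
        if self.abscissa.ndim != 1 or np.any(np.diff(self.abscissa) <= 0):
            raise ValidationError("OrderTable abscissa must be 1-D strictly increasing")
        if self.values.ndim != 2 or self.values.shape[1] != self.abscissa.size:
            raise ValidationError("OrderTable values must be (l_max+1, len(abscissa))")

    @property
    def l_max(self) -> int:
        return self.values.shape[0] - 1

    @classmethod
    def build(cls, func: Callable[[int, np.ndarray], np.ndarray], l_max: int,
              abscissa: np.ndarray) -> "OrderTable":
        """Tabulate ``func(l_max, abscissa)`` which must return (l_max+1, R)."""
        abscissa = np.asarray(abscissa, dtype=float)
        vals = np.asarray(func(l_max, abscissa))
        return cls(abscissa, vals)

    def interp(self, x) -> np.ndarray:
        """Linear interpolation of every order at ``x`` (clamped)."""
        x = np.clip(np.asarray(x, dtype=float), self.abscissa[0], self.abscissa[-1])
        idx = np.clip(np.searchsorted(self.abscissa, x) - 1, 0, self.abscissa.size - 2)
        x0 = self.abscissa[idx]
        x1 = self.abscissa[idx + 1]
        t = (x - x0) / (x1 - x0)
        return self.values[:, idx] * (1.0 - t) + self.values[:, idx + 1] * t

    def save(self, path) -> None:
        np.savez(path, abscissa=self.abscissa, values=self.values)

    @classmethod
    def load(cls, path) -> "OrderTable":
        with np.load(path) as data:
            return cls(data["abscissa"], data["values"])
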