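"""Complex refractive-index spectra: file loading, Lorentz-oscillator
synthesis, and the Kramers-Kronig route from absorbance measurements.

The canonical wavelength unit is micrometres throughout; wavenumber
(cm^-1) tables are converted at the I/O boundary via ``lam = 1e4 / nu``.
Queries outside the tabulated range clamp to the nearest endpoint rather
than extrapolate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert as _analytic_signal

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MaterialSpectrum",
    "kramers_kronig",
    "load_material_table",
    "lorentzian_fixture",
]

#: Baseline refractive index typical of polymers; default for the KK path.
DEFAULT_N0 = 1.4


@dataclass
class MaterialSpectrum:
    """Complex refractive index n(lam) = eta(lam) + i*kappa(lam).

    Attributes
    ----------
    wavelengths : ndarray
        Sample wavelengths in micrometres, strictly increasing, all > 0.
    eta : ndarray
        Real refractive index, > 0 everywhere.
    kappa : ndarray
        Extinction coefficient, >= 0 everywhere.
    n0 : float
        Baseline (off-resonance) refractive index.
    """

    wavelengths: np.ndarray
    eta: np.ndarray
    kappa: np.ndarray
    n0: float = DEFAULT_N0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 1:
            raise ValidationError("wavelengths must be a non-empty 1-D array")
        if self.eta.shape != self.wavelengths.shape or self.kappa.shape != self.wavelengths.shape:
            raise ValidationError("eta and kappa must match the wavelength grid")
        if np.any(self.wavelengths <= 0):
            raise ValidationError("wavelengths must all be > 0")
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.eta)) or not np.all(np.isfinite(self.kappa)):
            raise ValidationError("eta/kappa must be finite")
        if np.any(self.eta <= 0):
            raise ValidationError("eta must be > 0 everywhere")
        if np.any(self.kappa < 0):
            raise ValidationError("kappa must be >= 0 everywhere")

    def eta_at(self, lam) -> np.ndarray:
        """Real index at ``lam`` (um), linearly interpolated, clamped."""
        return np.interp(lam, self.wavelengths, self.eta)

    def kappa_at(self, lam) -> np.ndarray:
        """Extinction at ``lam`` (um), linearly interpolated, clamped."""
        return np.interp(lam, self.wavelengths, self.kappa)

    def n(self, lam):
        """Complex index eta + i*kappa at ``lam``."""
        return self.eta_at(lam) + 1j * self.kappa_at(lam)

    @classmethod
    def constant(cls, n: complex, n0: float | None = None) -> "MaterialSpectrum":
        """Dispersion-free material with index ``n`` at every wavelength."""
        n = complex(n)
        lam = np.array([0.1, 1e4])
        return cls(lam, np.full(2, n.real), np.full(2, n.imag),
                   n0=n.real if n0 is None else n0)


def load_material_table(path, units: str = "micron") -> MaterialSpectrum:
    """Read a 3-column delimited table (abscissa, eta, kappa).

    ``units`` selects the abscissa unit: ``"micron"`` or ``"inverse_cm"``
    (converted via lam[um] = 1e4 / nu[cm^-1] and re-sorted ascending).
    Comma or whitespace delimited; ``#`` starts a comment.
    """
    if units not in ("micron", "inverse_cm"):
        raise ValidationError(f"units must be 'micron' or 'inverse_cm', got {units!r}")
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, got {len(rows)}")
    data = np.asarray(rows, dtype=float)
    absc, eta, kappa = data[:, 0], data[:, 1], data[:, 2]
    if np.any(absc <= 0):
        raise ValidationError(f"{path}: non-positive abscissa value")
    if np.any(kappa < 0):
        raise ValidationError(f"{path}: negative kappa value")
    lam = 1e4 / absc if units == "inverse_cm" else absc
    order = np.argsort(lam)
    return MaterialSpectrum(lam[order], eta[order], kappa[order])


def _hilbert_partner(chi2: np.ndarray, pad_factor: int = 4) -> np.ndarray:
    """chi'(x) = (1/pi) PV integral chi''(x') / (x' - x) dx' on a uniform grid.

    Computed with a zero-padded FFT Hilbert transform; ``chi2`` must already
    include any symmetry extension the caller wants.
    """
    n = chi2.size
    padded = np.zeros(int(pad_factor) * n)
    start = (padded.size - n) // 2
    padded[start:start + n] = chi2
    # scipy's analytic signal: hilbert(x) = x + i H[x] with H[cos] = sin,
    # i.e. H[f](t) = (1/pi) PV int f(s)/(t-s) ds.  We need the opposite sign.
    partner = -np.imag(_analytic_signal(padded))
    return partner[start:start + n]


def kramers_kronig(wavelengths, absorbance, n0: float = DEFAULT_N0,
                   pad_factor: int = 4) -> MaterialSpectrum:
    """Complex index from a per-micrometre absorbance spectrum A(lam).

    The imaginary susceptibility is ``chi'' = A * lam * n0 / (2 pi)`` (sign
    fixed so that kappa >= 0 for A >= 0) and its dispersion partner chi' is
    obtained by a discrete Hilbert transform on a uniform wavenumber grid
    with odd symmetry about zero frequency.  Returns
    ``eta = n0 + chi'/(2 n0)`` and ``kappa = A * lam / (4 pi)``.

    Edge effects: chi'' is implicitly truncated to the tabulated range, so
    eta is reliable only away from the grid edges (roughly the inner 80% of
    the grid for a resonance that decays within the tabulated window).
    """
    lam = np.asarray(wavelengths, dtype=float)
    A = np.asarray(absorbance, dtype=float)
    if lam.ndim != 1 or lam.size < 16:
        raise ValidationError("kramers_kronig needs a 1-D grid of >= 16 samples")
    if A.shape != lam.shape:
        raise ValidationError("absorbance must match the wavelength grid")
    if not np.all(np.isfinite(lam)) or not np.all(np.isfinite(A)):
        raise ValidationError("non-finite values in kramers_kronig input")
    if np.any(lam <= 0):
        raise ValidationError("wavelengths must be > 0")
    if np.any(A < 0):
        raise ValidationError("absorbance must be >= 0")
    if n0 <= 0:
        raise ValidationError("n0 must be > 0")
    order = np.argsort(lam)
    lam, A = lam[order], A[order]

    kappa = A * lam / (4.0 * np.pi)
    chi2_lam = 2.0 * n0 * kappa  # chi'' on the wavelength grid

    # Dispersion integral lives in frequency: resample chi''(nu), nu = 1/lam,
    # onto a uniform grid reaching down to nu = 0, odd-extend, transform.
    nu = 1.0 / lam[::-1]
    chi2_nu = chi2_lam[::-1]
    dnu = (nu[-1] - nu[0]) / (8 * nu.size)
    nu_grid = np.arange(dnu, nu[-1] + dnu, dnu)
    chi2_grid = np.interp(nu_grid, nu, chi2_nu, left=0.0, right=0.0)
    # odd extension chi''(-nu) = -chi''(nu), with a zero at nu = 0
    full = np.concatenate([-chi2_grid[::-1], [0.0], chi2_grid])
    chi1_full = _hilbert_partner(full, pad_factor=max(4, pad_factor))
    chi1_grid = chi1_full[chi2_grid.size + 1:]
    chi1_lam = np.interp(1.0 / lam, nu_grid, chi1_grid)

    eta = n0 + chi1_lam / (2.0 * n0)
    return MaterialSpectrum(lam, eta, kappa, n0=n0)


def lorentzian_fixture(center_wavelengths, amplitudes, widths,
                       n0: float = DEFAULT_N0, grid=None) -> MaterialSpectrum:
    """Synthetic material: kappa is a sum of Lorentzian resonances and eta
    the matched analytic dispersion, so the pair is Kramers-Kronig
    consistent by construction.

    Each resonance is a damped oscillator in wavenumber space,
    ``chi(nu) = A0 / (nu0^2 - nu^2 - i g nu)`` with ``nu0 = 1/center`` and
    ``g = width / center^2`` (``width`` is the approximate FWHM in
    micrometres of wavelength); ``A0`` is scaled so the kappa peak height
    equals the given amplitude.  Deterministic.
    """
    centers = np.atleast_1d(np.asarray(center_wavelengths, dtype=float))
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), centers.shape)
    wids = np.broadcast_to(np.asarray(widths, dtype=float), centers.shape)
    if np.any(wids <= 0):
        raise ValidationError("widths must be > 0")
    if grid is None:
        grid = np.linspace(2.0, 12.0, 512)
    lam = np.asarray(grid, dtype=float)
    nu = 1.0 / lam
    chi1 = np.zeros_like(lam)
    chi2 = np.zeros_like(lam)
    for lam0, amp, w in zip(centers, amps, wids):
        if not (lam.min() <= lam0 <= lam.max()):
            logger.warning("lorentzian_fixture: peak at %.4g um lies outside the "
                           "grid [%.4g, %.4g]; adding it anyway",
                           lam0, lam.min(), lam.max())
        nu0 = 1.0 / lam0
        g = w / lam0 ** 2
        a0 = amp * 2.0 * n0 * g * nu0
        den = (nu0 ** 2 - nu ** 2) ** 2 + (g * nu) ** 2
        chi1 += a0 * (nu0 ** 2 - nu ** 2) / den
        chi2 += a0 * g * nu / den
    eta = n0 + chi1 / (2.0 * n0)
    kappa = chi2 / (2.0 * n0)
    return MaterialSpectrum(lam, eta, kappa, n0=n0)


def absorbance_from(material: MaterialSpectrum) -> np.ndarray:
    """Per-micrometre absorbance A(lam) = 4 pi kappa / lam of a material."""
    return 4.0 * np.pi * material.kappa / material.wavelengths
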