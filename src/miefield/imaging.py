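"""Fourier-optics image formation: objective band-pass, detector
intensity, absorbance, per-pixel spectra and extended incoherent sources.

The objective is modelled as an annular spatial-frequency mask with
cutoffs ``f_u = NA_o / lam`` and ``f_l = NA_in / lam`` applied to the FFT
of the focal-plane field slice (frequency step 1/S for a field of view S,
boundary frequencies pass).  Intensity is |field|^2 block-averaged onto
the detector grid; absorbance is -log10(I / I0) against a sphere-free
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, ValidationError
from .incident import FieldSlice
from .scatter import Scene, total_field

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorConfig",
    "Image",
    "absorbance_image",
    "detector_image",
    "extended_source_image",
    "focal_plane_slice",
    "objective_bandpass",
    "point_spectrum",
    "scene_images",
]

#: I0 below this fraction of its peak marks an absorbance pixel invalid.
I0_FLOOR = 1e-12

#: relative slack for boundary-inclusive frequency cutoffs.
_CUT_EPS = 1e-9


@dataclass
class DetectorConfig:
    """Objective NA pair plus field/detector sampling.

    ``resolution`` is the field-slice sampling (R per side over the field
    of view ``fov``); ``det_pixels`` the detector samples per side, which
    must divide R for block resampling.
    """

    na_out: float
    na_in: float
    fov: float
    resolution: int
    det_pixels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.na_in < self.na_out <= 1.0):
            raise ValidationError(
                f"require 0 <= NA_in < NA_out <= 1, got ({self.na_in}, {self.na_out})")
        if self.fov <= 0:
            raise ValidationError("fov must be > 0")
        if self.det_pixels < 1 or self.det_pixels > self.resolution:
            raise ValidationError("det_pixels must be in [1, resolution]")
        if self.resolution % self.det_pixels != 0:
            near = max(d for d in range(1, self.resolution + 1)
                       if self.resolution % d == 0 and d <= self.det_pixels)
            raise ValidationError(
                f"resolution {self.resolution} not divisible by det_pixels "
                f"{self.det_pixels}; nearest valid det_pixels is {near}")

    def cutoffs(self, lam: float):
        """(f_l, f_u) = (NA_in, NA_o) / lam in cycles per micrometre."""
        return self.na_in / lam, self.na_out / lam


@dataclass
class Image:
    """Real detector-plane image with per-pixel validity mask."""

    values: np.ndarray
    pixel_size: float
    kind: str  # "intensity" | "absorbance"
    mask: np.ndarray | None = None  # True where the pixel is invalid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "intensity" and np.any(self.values < 0):
            raise ValidationError("intensity image must be >= 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape must match image")


def objective_bandpass(field_slice: FieldSlice, det: DetectorConfig,
                       lam: float) -> FieldSlice:
    """Annular spatial-frequency mask applied to a square field slice.

    Components with radial frequency strictly above f_u = NA_o/lam or
    strictly below f_l = NA_in/lam are removed; boundary frequencies pass.
    Applying the filter twice equals applying it once (projection).
    """
    if field_slice.samples is None:
        raise ValidationError("field slice has no samples")
    R = field_slice.resolution
    S = field_slice.extent
    f_l, f_u = det.cutoffs(lam)
    freq = np.fft.fftfreq(R, d=S / R)  # step 1/S
    rad = np.hypot(freq[:, None], freq[None, :])
    keep = (rad <= f_u * (1.0 + _CUT_EPS) + _CUT_EPS) \
        & (rad >= f_l * (1.0 - _CUT_EPS) - _CUT_EPS)
    filtered = np.fft.ifft2(np.fft.fft2(field_slice.samples) * keep)
    return field_slice.with_samples(filtered)


def detector_image(filtered: FieldSlice, det: DetectorConfig) -> Image:
    """|field|^2 at slice resolution, block-averaged onto the detector grid."""
    if filtered.samples is None:
        raise ValidationError("field slice has no samples")
    R, D = filtered.resolution, det.det_pixels
    if R % D != 0:
        raise ValidationError(f"resolution {R} not divisible by det_pixels {D}")
    b = R // D
    intensity = np.abs(filtered.samples) ** 2
    binned = intensity.reshape(D, b, D, b).mean(axis=(1, 3))
    return Image(values=binned, pixel_size=filtered.extent / D, kind="intensity")


def absorbance_image(image: Image, reference: Image) -> Image:
    """A = -log10(I / I0); pixels with I0 below the floor are masked."""
    if image.values.shape != reference.values.shape:
        raise GeometryError("image geometries differ (shape)")
    if abs(image.pixel_size - reference.pixel_size) > 1e-12 * reference.pixel_size:
        raise GeometryError("image geometries differ (pixel size)")
    i0 = reference.values
    invalid = i0 < I0_FLOOR * np.max(i0)
    safe_i0 = np.where(invalid, 1.0, i0)
    safe_i = np.where(invalid, 1.0, image.values)
    with np.errstate(divide="ignore"):
        a = -np.log10(safe_i / safe_i0)
    a[invalid] = 0.0
    return Image(values=a, pixel_size=image.pixel_size, kind="absorbance",
                 mask=invalid)


def focal_plane_slice(scene: Scene, det: DetectorConfig) -> FieldSlice:
    """Total field evaluated on the focal (image) plane through p_f."""
    sl = FieldSlice(origin=scene.config.p_f, axis_u=[1.0, 0.0, 0.0],
                    axis_v=[0.0, 1.0, 0.0], extent=det.fov,
                    resolution=det.resolution)
    return sl.with_samples(total_field(scene, sl.grid_points()))


def scene_images(scene: Scene, det: DetectorConfig):
    """(intensity, reference intensity, absorbance) for one wavelength."""
    lam = scene.config.lam
    img = detector_image(objective_bandpass(focal_plane_slice(scene, det),
                                            det, lam), det)
    ref = detector_image(objective_bandpass(
        focal_plane_slice(scene.without_spheres(), det), det, lam), det)
    return img, ref, absorbance_image(img, ref)


def point_spectrum(scene: Scene, det: DetectorConfig, pixel, wavelengths) -> np.ndarray:
    """Absorbance spectrum A(lam) at one detector pixel.

    Runs the full coherent pipeline (materials -> fields -> imaging) per
    wavelength; the series order is re-derived per wavelength.  Material
    tables not covering a wavelength clamp to their nearest endpoint.
    """
    i, j = pixel
    if not (0 <= i < det.det_pixels and 0 <= j < det.det_pixels):
        raise ValidationError(f"pixel {pixel} outside detector grid")
    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    for s in scene.spheres:
        if s.material is not None:
            w = s.material.wavelengths
            lo, hi = wavelengths.min(), wavelengths.max()
            if lo < w[0] or hi > w[-1]:
                logger.warning("point_spectrum: material grid [%.4g, %.4g] um does "
                               "not cover requested range [%.4g, %.4g]; clamping",
                               w[0], w[-1], lo, hi)
    spectrum = np.empty(wavelengths.size)
    for idx, lam in enumerate(wavelengths):
        _, _, absorb = scene_images(scene.with_wavelength(float(lam)), det)
        spectrum[idx] = absorb.values[i, j]
    return spectrum


def extended_source_image(scene: Scene, det: DetectorConfig, source_map,
                          spacing: float) -> Image:
    """Incoherent extended source: weighted sum of point-source intensities.

    Each source-map sample laterally displaces the condenser focal point by
    its pixel offset times ``spacing`` (map centered on the axis), runs the
    coherent pipeline, and the intensity images are averaged with the
    sample weights (normalized by total weight).  The image plane stays
    fixed.  Use a sphere-free scene to obtain the matching reference.
    """
    weights = np.atleast_2d(np.asarray(source_map, dtype=float))
    if np.any(weights < 0):
        raise ValidationError("source map weights must be >= 0")
    total_w = weights.sum()
    if total_w <= 0:
        raise ValidationError("source map weights must sum to > 0")
    h, w = weights.shape
    lam = scene.config.lam
    accum = None
    for i in range(h):
        for j in range(w):
            wt = weights[i, j]
            if wt == 0:
                continue
            offset = np.array([(i - (h - 1) / 2.0) * spacing,
                               (j - (w - 1) / 2.0) * spacing, 0.0])
            shifted = scene.with_focus(scene.config.p_f + offset)
            sl = FieldSlice(origin=scene.config.p_f, axis_u=[1.0, 0.0, 0.0],
                            axis_v=[0.0, 1.0, 0.0], extent=det.fov,
                            resolution=det.resolution)
            sl = sl.with_samples(total_field(shifted, sl.grid_points()))
            img = detector_image(objective_bandpass(sl, det, lam), det)
            accum = wt * img.values if accum is None else accum + wt * img.values
    return Image(values=accum / total_w, pixel_size=det.fov / det.det_pixels,
                 kind="intensity")
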