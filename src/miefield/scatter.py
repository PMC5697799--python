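"""Per-sphere scattering: series coefficients, single-plane-wave internal
and external fields with the off-focus phase shift, scatter-domain tables,
stratified Monte-Carlo aperture integration, scene superposition and
sphere-surface fields.

A sphere displaced from the focal point by ``c = p_s - p_f`` scatters each
aperture plane wave with direction ``d`` multiplied by the phase factor
``exp(i k d . c)``; the remaining series depends only on the distance from
the sphere center and the angle to ``d``, which is what the 2-D scatter
domain tabulates.  Spheres superpose without inter-sphere coupling (first
Born / single-scattering approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GeometryError, ValidationError
from .incident import OpticalConfig, focused_field
from .materials import MaterialSpectrum
from .sphmath import (
    legendre_sequence,
    max_order,
    spherical_bessel_family,
    spherical_jn_all,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MCSampling",
    "Scene",
    "ScatterDomain",
    "ScatteringCoefficients",
    "Sphere",
    "SurfaceMesh",
    "aperture_samples",
    "icosphere",
    "mc_sphere_field",
    "planewave_sphere_field",
    "sample_scatter_domain",
    "scatter_domain",
    "scattering_coefficients",
    "surface_field",
    "total_field",
]

#: relative tolerance under which a point counts as "on" the sphere surface
#: (such points evaluate the internal branch; both branches agree there).
SURFACE_TOL = 1e-9

#: decay demanded of the highest-order coefficient relative to the peak.
DECAY_TOL = 1e-6


@dataclass
class Sphere:
    """Homogeneous sphere: center (um), radius a (um), material reference."""

    center: np.ndarray
    radius: float
    material: MaterialSpectrum | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValidationError("sphere radius must be > 0")

    def offset(self, p_f) -> np.ndarray:
        """c = p_s - p_f, the vector driving the per-plane-wave phase shift."""
        return self.center - np.asarray(p_f, dtype=float).reshape(3)


@dataclass
class ScatteringCoefficients:
    """Per-order couplings: A_l scales the internal series (j_l(k n r)),
    B_l the external scattered series (h1_l(k r))."""

    A: np.ndarray
    B: np.ndarray
    lam: float
    n: complex
    N_l: int

    @property
    def l_max(self) -> int:
        return self.N_l


def _coefficient_arrays(a: float, n: complex, lam: float, N: int):
    k = 2.0 * np.pi / lam
    x = k * a
    z = complex(n) * x
    fam = spherical_bessel_family(N, x)
    j_z, dj_z = spherical_jn_all(N, np.asarray(z, dtype=complex), derivative=True)
    l = np.arange(N + 1)
    pref = (2 * l + 1) * 1j ** l
    denom = j_z * fam.dh1 - fam.h1 * dj_z * n
    scale = np.abs(j_z * fam.dh1) + np.abs(fam.h1 * dj_z * n)
    bad = np.abs(denom) <= 1e-14 * scale
    if np.any(bad):
        lb = int(np.argmax(bad))
        raise ValidationError(
            f"scattering resonance at numerical precision: l={lb}, ka={x:.6g}, n={n}"
        )
    B = pref * (fam.j * dj_z * n - j_z * fam.dj) / denom
    A = pref * (fam.j * fam.dh1 - fam.dj * fam.h1) / denom
    return A, B


def scattering_coefficients(a: float, n: complex, lam: float,
                            l_max: int | None = None) -> ScatteringCoefficients:
    """Internal/external series coefficients for a sphere of radius ``a``.

    The order runs to the Bohren-Huffman bound for size parameter ka and is
    raised automatically until the final coefficient magnitude has decayed
    below ``DECAY_TOL`` times the peak.
    """
    if a <= 0 or lam <= 0:
        raise ValidationError("require a > 0 and lam > 0")
    n = complex(n)
    if n.imag < 0:
        raise ValidationError("Im(n) must be >= 0 (absorbing or transparent)")
    N = max_order(a, lam) if l_max is None else int(l_max)
    cap = 2 * N + 64
    while True:
        A, B = _coefficient_arrays(a, n, lam, N)
        b_peak = np.max(np.abs(B))
        if b_peak == 0.0 or np.abs(B[-1]) < DECAY_TOL * b_peak or N >= cap:
            break
        N += 4
    return ScatteringCoefficients(A=A, B=B, lam=lam, n=n, N_l=N)


def _branch_masks(r: np.ndarray, a: float, branch: str):
    if branch == "auto":
        inside = r <= a * (1.0 + SURFACE_TOL)
    elif branch == "internal":
        inside = np.ones_like(r, dtype=bool)
    elif branch == "external":
        inside = np.zeros_like(r, dtype=bool)
    else:
        raise ValidationError(f"unknown branch {branch!r}")
    return inside, ~inside


def planewave_sphere_field(sphere: Sphere, coeffs: ScatteringCoefficients,
                           direction, p_f, points,
                           branch: str = "auto") -> np.ndarray:
    """Field of a single incident plane wave scattered by one sphere.

    Outside the sphere the value is the scattered part only,
    ``exp(i k d.c) sum_l B_l h1_l(k r) P_l(cos t)``; inside it is the total
    internal field ``exp(i k d.c) sum_l A_l j_l(k n r) P_l(cos t)`` where
    ``cos t`` is measured between ``d`` and the point offset from the
    sphere center.  ``branch`` forces a branch for boundary studies.
    """
    d = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(d)
    if abs(norm - 1.0) > 1e-9:
        logger.warning("planewave_sphere_field: normalizing direction (|d|=%.6g)", norm)
        d = d / norm
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - sphere.center[None, :]
    r = np.linalg.norm(rel, axis=1)
    ct = np.where(r > 0, (rel @ d) / np.where(r > 0, r, 1.0), 1.0)
    ct = np.clip(ct, -1.0, 1.0)
    k = 2.0 * np.pi / coeffs.lam
    phase = np.exp(1j * k * (d @ sphere.offset(p_f)))
    L = coeffs.N_l
    out = np.zeros(pts.shape[0], dtype=complex)
    inside, outside = _branch_masks(r, sphere.radius, branch)
    if np.any(outside):
        h1 = spherical_bessel_family(L, r[outside] * k).h1
        P = legendre_sequence(L, ct[outside])
        out[outside] = coeffs.B @ (h1 * P)
    if np.any(inside):
        j = spherical_jn_all(L, (coeffs.n * k * r[inside]).astype(complex))
        P = legendre_sequence(L, ct[inside])
        out[inside] = coeffs.A @ (j * P)
    return phase * out


@dataclass
class ScatterDomain:
    """2-D table of the un-phase-shifted single-plane-wave field over
    (distance from sphere center d, cos of the angle to the propagation
    direction).  Internal samples cover d < a, external d >= a."""

    d_axis: np.ndarray
    costheta_axis: np.ndarray
    values: np.ndarray  # (R, R_theta) complex; internal/external merged at d = a
    radius: float

    def __post_init__(self) -> None:
        self.d_axis = np.asarray(self.d_axis, dtype=float)
        self.costheta_axis = np.asarray(self.costheta_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (self.d_axis.size, self.costheta_axis.size):
            raise ValidationError("scatter domain shape mismatch")

    @property
    def external(self) -> np.ndarray:
        return self.values[self.d_axis >= self.radius]

    @property
    def internal(self) -> np.ndarray:
        return self.values[self.d_axis < self.radius]


def scatter_domain(sphere: Sphere, coeffs: ScatteringCoefficients, fov: float,
                   resolution: int, r_theta: int = 1000) -> ScatterDomain:
    """Tabulate the single-plane-wave field over d in [0, fov/2] x cos t in [-1, 1].

    ``r_theta`` must satisfy the Nyquist rule ``R_theta >= 2 N_l`` so the
    fastest Legendre oscillation is resolved (default 1000).
    """
    if r_theta < 2 * coeffs.N_l:
        logger.warning("scatter_domain: R_theta=%d below the Nyquist rule "
                       "2*N_l=%d; interpolation will alias", r_theta, 2 * coeffs.N_l)
    d_axis = np.linspace(0.0, fov / 2.0, resolution)
    ct_axis = np.linspace(-1.0, 1.0, r_theta)
    k = 2.0 * np.pi / coeffs.lam
    L = coeffs.N_l
    P = legendre_sequence(L, ct_axis)  # (L+1, R_theta)
    inside = d_axis < sphere.radius * (1.0 + SURFACE_TOL)
    vals = np.empty((resolution, r_theta), dtype=complex)
    if np.any(inside):
        j = spherical_jn_all(L, (coeffs.n * k * d_axis[inside]).astype(complex))
        vals[inside] = (coeffs.A[:, None] * j).T @ P
    if np.any(~inside):
        h1 = spherical_bessel_family(L, k * d_axis[~inside]).h1
        vals[~inside] = (coeffs.B[:, None] * h1).T @ P
    return ScatterDomain(d_axis, ct_axis, vals, sphere.radius)


def sample_scatter_domain(domain: ScatterDomain, d, costheta,
                          phase: complex = 1.0 + 0.0j) -> np.ndarray:
    """Bilinear lookup; multiply by the caller's plane-wave phase factor."""
    d = np.atleast_1d(np.asarray(d, dtype=float))
    ct = np.atleast_1d(np.asarray(costheta, dtype=float))
    if np.any(d > domain.d_axis[-1] + 1e-12):
        logger.warning("sample_scatter_domain: d beyond fov/2; clamping")
    d = np.clip(d, domain.d_axis[0], domain.d_axis[-1])
    ct = np.clip(ct, -1.0, 1.0)
    i = np.clip(np.searchsorted(domain.d_axis, d) - 1, 0, domain.d_axis.size - 2)
    j = np.clip(np.searchsorted(domain.costheta_axis, ct) - 1, 0,
                domain.costheta_axis.size - 2)
    tx = (d - domain.d_axis[i]) / (domain.d_axis[i + 1] - domain.d_axis[i])
    ty = (ct - domain.costheta_axis[j]) / (
        domain.costheta_axis[j + 1] - domain.costheta_axis[j])
    v = ((1 - tx) * (1 - ty) * domain.values[i, j]
         + tx * (1 - ty) * domain.values[i + 1, j]
         + (1 - tx) * ty * domain.values[i, j + 1]
         + tx * ty * domain.values[i + 1, j + 1])
    return phase * v


@dataclass
class MCSampling:
    """Deterministic jittered-stratified plane-wave directions over the
    annular aperture cap (uniform in (phi, z) by Archimedes' principle)."""

    M: int
    seed: int
    alpha1: float
    alpha2: float
    directions: np.ndarray  # (M, 3) unit vectors

    @property
    def solid_angle(self) -> float:
        return 2.0 * np.pi * (np.cos(self.alpha1) - np.cos(self.alpha2))


def aperture_samples(alpha1: float, alpha2: float, M: int, seed: int) -> MCSampling:
    """Latin-hypercube jittered stratified samples on the aperture cap.

    phi and z = cos(theta) are each divided into M strata, jittered within
    each stratum and randomly paired; the (phi, z) pairs are projected onto
    the unit sphere.  Bit-reproducible for a given seed.
    """
    if M < 1:
        raise ValidationError("M must be >= 1")
    if not (0.0 <= alpha1 < alpha2 <= np.pi):
        raise ValidationError(f"require 0 <= alpha1 < alpha2 <= pi, got ({alpha1}, {alpha2})")
    rng = np.random.default_rng(seed)
    z_lo, z_hi = np.cos(alpha2), np.cos(alpha1)
    z = z_lo + (z_hi - z_lo) * (rng.permutation(M) + rng.random(M)) / M
    phi = 2.0 * np.pi * (np.arange(M) + rng.random(M)) / M
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    directions = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    return MCSampling(M=M, seed=seed, alpha1=alpha1, alpha2=alpha2,
                      directions=directions)


def mc_sphere_field(sphere: Sphere, coeffs: ScatteringCoefficients,
                    sampling: MCSampling, config: OpticalConfig, points,
                    branch: str = "auto", chunk: int = 128) -> np.ndarray:
    """Aperture-integrated sphere field estimated by Monte-Carlo:

    ``(2 pi E0 (cos a1 - cos a2) / M) * sum_j planewave_sphere_field(d_j)``.

    The radial special functions depend only on |p - p_s| and are shared
    across all directions, so each sample costs one Legendre recursion.
    """
    if (abs(sampling.alpha1 - config.alpha1) > 1e-9
            or abs(sampling.alpha2 - config.alpha2) > 1e-9):
        logger.warning("mc_sphere_field: sampling aperture (%.4g, %.4g) differs "
                       "from config aperture (%.4g, %.4g)",
                       sampling.alpha1, sampling.alpha2,
                       config.alpha1, config.alpha2)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - sphere.center[None, :]
    r = np.linalg.norm(rel, axis=1)
    k = config.k
    L = coeffs.N_l
    inside, outside = _branch_masks(r, sphere.radius, branch)
    c = sphere.offset(config.p_f)
    out = np.zeros(pts.shape[0], dtype=complex)
    for mask, radial in _radial_factors(coeffs, k, r, inside, outside):
        if not np.any(mask):
            continue
        rel_m = rel[mask]
        r_m = np.where(r[mask] > 0, r[mask], 1.0)
        origin = r[mask] == 0
        acc_total = np.zeros(rel_m.shape[0], dtype=complex)
        for s in range(0, sampling.M, chunk):
            d = sampling.directions[s:s + chunk]          # (m, 3)
            phase = np.exp(1j * k * (d @ c))              # (m,)
            ct = (d @ rel_m.T) / r_m[None, :]             # (m, n)
            if np.any(origin):
                ct[:, origin] = 1.0
            ct = np.clip(ct, -1.0, 1.0)
            # Legendre recursion with on-the-fly accumulation over orders
            p_prev = np.ones_like(ct)
            acc = radial[0] * p_prev
            if L >= 1:
                p_cur = ct
                acc = acc + radial[1] * p_cur
                for l in range(2, L + 1):
                    p_prev, p_cur = p_cur, ((2 * l - 1) * ct * p_cur
                                            - (l - 1) * p_prev) / l
                    acc = acc + radial[l] * p_cur
            acc_total += phase @ acc
        out[mask] = acc_total
    pref = 2.0 * np.pi * config.E0 * (np.cos(config.alpha1)
                                      - np.cos(config.alpha2)) / sampling.M
    return pref * out


def _radial_factors(coeffs, k, r, inside, outside):
    """Yield (mask, per-order radial factors) for the two branches."""
    if np.any(outside):
        h1 = spherical_bessel_family(coeffs.N_l, k * r[outside]).h1
        yield outside, coeffs.B[:, None] * h1
    if np.any(inside):
        j = spherical_jn_all(coeffs.N_l, (coeffs.n * k * r[inside]).astype(complex))
        yield inside, coeffs.A[:, None] * j


@dataclass
class Scene:
    """Spheres + illumination + shared Monte-Carlo direction set.

    All spheres share one direction set per wavelength: physically they see
    the same plane-wave decomposition of the incident beam, and sharing
    preserves inter-sphere coherence.
    """

    spheres: list
    config: OpticalConfig
    sampling: MCSampling | None = None

    def __post_init__(self) -> None:
        for i in range(len(self.spheres)):
            for j in range(i + 1, len(self.spheres)):
                si, sj = self.spheres[i], self.spheres[j]
                gap = np.linalg.norm(si.center - sj.center)
                if gap < si.radius + sj.radius:
                    logger.warning("Scene: spheres %d and %d overlap "
                                   "(center distance %.4g < %.4g)",
                                   i, j, gap, si.radius + sj.radius)

    def with_wavelength(self, lam: float) -> "Scene":
        return Scene(self.spheres, self.config.with_wavelength(lam), self.sampling)

    def with_focus(self, p_f) -> "Scene":
        return Scene(self.spheres, self.config.with_focus(p_f), self.sampling)

    def without_spheres(self) -> "Scene":
        return Scene([], self.config, self.sampling)

    def coefficients(self) -> list:
        """Scattering coefficients of every sphere at the scene wavelength."""
        out = []
        for s in self.spheres:
            if s.material is None:
                raise ValidationError("scene sphere lacks a material")
            out.append(scattering_coefficients(
                s.radius, complex(s.material.n(self.config.lam)), self.config.lam))
        return out


def total_field(scene: Scene, points) -> np.ndarray:
    """Total field: focused + superposed scattered fields outside spheres,
    per-sphere internal field inside (single-scattering approximation)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts = pts.shape[0]
    inside_masks = []
    for s in scene.spheres:
        r = np.linalg.norm(pts - s.center[None, :], axis=1)
        inside_masks.append(r <= s.radius * (1.0 + SURFACE_TOL))
    if inside_masks:
        counts = np.sum(inside_masks, axis=0)
        if np.any(counts > 1):
            raise GeometryError("point lies inside two spheres (overlapping scene)")
        outside = counts == 0
    else:
        outside = np.ones(n_pts, dtype=bool)
    out = np.zeros(n_pts, dtype=complex)
    out[outside] = focused_field(scene.config, pts[outside])
    if scene.spheres:
        if scene.sampling is None:
            raise ValidationError("Scene.sampling is required when spheres are present")
        all_coeffs = scene.coefficients()
        for s, coeffs, inside in zip(scene.spheres, all_coeffs, inside_masks):
            if np.any(outside):
                out[outside] += mc_sphere_field(s, coeffs, scene.sampling,
                                                scene.config, pts[outside],
                                                branch="external")
            if np.any(inside):
                out[inside] = mc_sphere_field(s, coeffs, scene.sampling,
                                              scene.config, pts[inside],
                                              branch="internal")
    return out


# ---------------------------------------------------------------------------
# surface fields

_ICO_LEVELS = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4}


def icosphere(level: int):
    """Unit icosphere by repeated midpoint subdivision of an icosahedron.

    Returns (vertices (V, 3), faces (F, 3)); V = 10 * 4**level + 2.
    """
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(level):
        cache: dict = {}
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.array(verts[i]) + np.array(verts[j])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts, dtype=float), np.array(faces, dtype=int)


@dataclass
class SurfaceMesh:
    """Triangulated sphere surface with a complex field value per vertex."""

    positions: np.ndarray
    faces: np.ndarray
    values: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def write_ply(self, path) -> None:
        """ASCII PLY with per-vertex magnitude/real/imag scalar properties."""
        with open(path, "w", encoding="ascii") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {self.positions.shape[0]}\n")
            for prop in ("x", "y", "z", "magnitude", "real", "imag"):
                fh.write(f"property float {prop}\n")
            fh.write(f"element face {self.faces.shape[0]}\n")
            fh.write("property list uchar int vertex_indices\n")
            fh.write("end_header\n")
            for p, v in zip(self.positions, self.values):
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} "
                         f"{abs(v):.9g} {v.real:.9g} {v.imag:.9g}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def surface_field(sphere: Sphere, scene: Scene, n_vertices: int = 162) -> SurfaceMesh:
    """Total field sampled on an icosphere scaled to the sphere surface.

    Surface points evaluate the internal branch; internal and external
    series agree there by construction.
    """
    if n_vertices not in _ICO_LEVELS:
        raise ValidationError(
            f"n_vertices must be one of {sorted(_ICO_LEVELS)} (icosphere counts)")
    verts, faces = icosphere(_ICO_LEVELS[n_vertices])
    positions = sphere.center[None, :] + sphere.radius * verts
    values = total_field(scene, positions)
    return SurfaceMesh(positions=positions, faces=faces, values=values)
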