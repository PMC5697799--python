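# miefield

Forward model for broadband mid-infrared microscopy of micro-spheres: a
scalar field focused by an annular (lens or Schwarzschild/cassegrain)
condenser is scattered by homogeneous spheres placed anywhere in the focal
volume, collected by a band-limiting objective and recorded as intensity
or absorbance images and per-pixel spectra.

The physics is the classical partial-wave machinery:

* **Focused incident field** — closed-form Legendre/spherical-Bessel series
  for an annular aperture between polar angles `arcsin(NA_in)` and
  `arcsin(NA_out)`, with an optional circularly-symmetric lookup-table cache.
* **Per-sphere scattering** — Mie series coefficients coupling the internal
  (`j_l(k n r)`) and external scattered (`h1_l(k r)`) fields; spheres away
  from the focal point pick up a per-plane-wave phase factor `exp(i k d·c)`.
* **Aperture integration** — deterministic jittered-stratified Monte-Carlo
  sampling of plane-wave directions over the condenser cap (uniform in
  `(phi, cos theta)`), shared across all spheres at a wavelength.
* **Image formation** — Fourier-optics annular band-pass with cutoffs
  `NA/lambda`, detector block-averaging, absorbance `-log10(I/I0)` against a
  sphere-free reference, extended incoherent sources as weighted sums of
  displaced point sources.
* **Materials** — complex refractive-index tables (µm or cm⁻¹), synthetic
  Lorentz-oscillator fixtures, and a Kramers-Kronig path from per-µm
  absorbance spectra.

Multiple spheres superpose without inter-sphere coupling (first Born /
single-scattering approximation).

## Command line

```sh
miefield --lambda 2.5 --na-cond 0.0,0.2 --na-obj 0.0,0.62 \
         --fov 16 --res 128 --det 64 --samples 400 --seed 1 \
         --material poly=const:1.49,0.01 \
         --sphere=-4,0,0,1,poly --sphere 0,0,0,1,poly --sphere 4,0,0,1,poly \
         --products nearfield,detector,absorbance,surface,spectrum \
         --out out/
```

Flat `key = value` configuration files are accepted via `--config`, with
CLI flags overriding file values; see `examples/three_spheres.cfg`
(three-sphere demo scene) and `examples/mc_convergence.cfg` (Monte-Carlo
convergence study scene).  Materials can be delimited text tables
(`id=path` or `id=path:inverse_cm`), constants (`id=const:eta,kappa`) or
Lorentz fixtures (`id=lorentz:center,amp,width,n0,lo,hi`).

Outputs are plain text: raw arrays (`.txt`), normalized 16-bit ASCII PGM
previews with `.minmax.txt` sidecars, ASCII PLY surface meshes, CSV
spectra, and a JSON manifest recording the config hash, seed and file
list.  A given (config, seed) pair reproduces outputs byte-for-byte.

## Layout

| module                | contents |
| --------------------- | -------- |
| `miefield.sphmath`    | spherical Bessel/Hankel/Legendre kernel, aperture coefficients, convergence order |
| `miefield.materials`  | refractive-index spectra, Lorentz fixtures, Kramers-Kronig |
| `miefield.incident`   | focused field, plane waves, lookup-table cache |
| `miefield.scatter`    | Mie coefficients, plane-wave/Monte-Carlo sphere fields, scenes, surface meshes |
| `miefield.imaging`    | objective band-pass, detector images, absorbance, spectra, extended sources |
| `miefield.cli`        | configuration, orchestration, product writers, console entry point |
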