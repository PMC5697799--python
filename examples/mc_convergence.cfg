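# Monte-Carlo convergence study scene: a 3 um particle in a 2.5 um field
# focused by a 0.8 NA condenser.  Run with increasing mc_samples
# (e.g. 4, 40, 400, 4000) and a fixed seed to watch the near-field noise
# fall off as 1/sqrt(M).
wavelengths = 2.5
na_cond = 0.0,0.8
na_obj = 0.0,0.8
fov = 10
resolution = 128
det_pixels = 64
mc_samples = 400
seed = 1
products = nearfield,surface
slice_origin = 0,0,0
slice_normal = 0,1,0
material = particle=const:1.4,0.05
sphere = 0,0,0,1.5,particle
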