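# Three identical 2 um diameter spheres separated by 2 um of vacuum,
# illuminated by a 0.2 NA condenser at 2.5 um.  Renders the near-field
# cross-section through the spheres, the detector/absorbance images and
# the per-sphere surface fields.
wavelengths = 2.5
na_cond = 0.0,0.2
na_obj = 0.0,0.62
fov = 16
resolution = 128
det_pixels = 64
mc_samples = 400
seed = 1
products = nearfield,detector,absorbance,surface
slice_origin = 0,0,0
slice_normal = 0,1,0
material = poly=const:1.49,0.01
sphere = -4,0,0,1.0,poly
sphere = 0,0,0,1.0,poly
sphere = 4,0,0,1.0,poly
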