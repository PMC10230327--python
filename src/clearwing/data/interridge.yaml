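# Interridge scale model with the microrib grating pre-homogenized
# (fill 62/(62+58), volume-weighted permittivity).
name: interridge
ambient: air
substrate: air
materials:
  chitin: {n: 1.56, k: 0.0}
  microrib_effective: {n: 1.3194, k: 0.0}
layers:
  - {material: microrib_effective, thickness_nm: 45}
  - {material: chitin, thickness_nm: 225}    # lower lamina
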