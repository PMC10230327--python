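# Planar core of the three-layer wing membrane (nipple arrays are added by
# the builders; see clearwing.wing_models.build_membrane).
name: membrane_three_layer
ambient: air
substrate: air
materials:
  chitin: {n: 1.56, k: 0.0}
  pigment: {n: 1.74, k: 0.010}
layers:
  - {material: chitin, thickness_nm: 436}    # dorsal exocuticle
  - {material: pigment, thickness_nm: 194}   # pigmented mesocuticle
  - {material: chitin, thickness_nm: 412}    # ventral exocuticle
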