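#!/usr/bin/env python
"""Membrane transparency: why the clearwing window is see-through and blue.

Builds the wing-membrane optical models from the measured ultrastructure
(dorsal exocuticle 436 nm / pigmented mesocuticle 194 nm / ventral
exocuticle 412 nm, half-ellipsoid nipple arrays 142 x 135 nm at 300 nm
pitch on both faces) and compares:

* one-layer vs three-layer models — the pigmented mesocuticle turns the
  evenly spaced slab fringes into a bimodal blue/orange-red signature;
* with vs without the nipple array — the graded-index coating suppresses
  reflection and pushes visible transmittance above 80%;
* steady-state reflected-field magnitudes at the two reflectance peaks and
  the dip, from continuous-wave FDTD runs, cross-checked against sqrt(R).

Writes spectra and summary tables under results/membrane/.
"""

from clearwing.pipeline import RunConfig, run_membrane_analysis

cfg = RunConfig(analysis="membrane", method="both", out_dir="results/membrane", seed=1)
report = run_membrane_analysis(cfg)

tri = report.extrema_nm
print("Three-layer + nipple membrane (graded-EMT TMM, 400-700 nm):")
print(f"  reflectance peaks at {tri['short_peak']:.0f} and {tri['long_peak']:.0f} nm, "
      f"dip at {tri['dip']:.0f} nm")
print(f"  minimum visible transmittance: {100 * report.transmittance_min:.1f}% "
      f"({'exceeds' if report.transmittance_ok else 'below'} the 80% transparency bound)")
print(f"  dominant maxima: one-layer model {report.one_layer_n_maxima} (multi-fringe), "
      f"nippled three-layer {report.three_layer_n_maxima} (bimodal)")
print("Reflected-field magnitudes above the source (CW FDTD vs sqrt R):")
for key in ("short_peak", "dip", "long_peak"):
    fdtd = report.field_magnitudes.get(key)
    print(f"  {key:10s} @ {tri[key]:.0f} nm: FDTD {fdtd:.3f}  sqrt(R) {report.sqrt_R[key]:.3f}")
print("Outputs in results/membrane/")
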