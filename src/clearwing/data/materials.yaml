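# Optical constants used throughout the wing models.
air:
  n: 1.0
  k: 0.0
chitin:
  n: 1.56
  k: 0.0
pigment:
  n: 1.74
  k: 0.010   # constant default; visible-range bound is k < 0.012
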