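acetic_acid
     RDKit          3D

  8  7  0  0  0  0  0  0  0  0999 V2000
   -0.9513   -0.1500   -0.0258 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.4653    0.3180   -0.0774 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8554    1.4120   -0.4467 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.3321   -0.6220    0.3421 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2219   -0.3991    1.0032 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0789   -1.0175   -0.6778 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6095    0.6502   -0.3761 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.2088   -0.1917    0.2584 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  2  4  1  0
  1  5  1  0
  1  6  1  0
  1  7  1  0
  4  8  1  0
M  END
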