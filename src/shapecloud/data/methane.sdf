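methane
     RDKit          3D

  5  4  0  0  0  0  0  0  0  0999 V2000
   -0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6890   -0.8423   -0.0934 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4171    0.8701   -0.5118 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.1468    0.2348    1.0565 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.9593   -0.2626   -0.4513 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
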