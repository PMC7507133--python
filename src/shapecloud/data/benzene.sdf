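benzene
     RDKit          3D

 12 12  0  0  0  0  0  0  0  0999 V2000
    0.9856    0.9866   -0.0288 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3619    1.3469   -0.0209 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3475    0.3603    0.0079 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9856   -0.9866    0.0288 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3619   -1.3469    0.0209 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3475   -0.3603   -0.0079 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.7534    1.7553   -0.0512 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6439    2.3963   -0.0372 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.3973    0.6410    0.0141 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7534   -1.7553    0.0512 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6439   -2.3963    0.0371 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.3973   -0.6410   -0.0141 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  1  7  1  0
  2  8  1  0
  3  9  1  0
  4 10  1  0
  5 11  1  0
  6 12  1  0
M  END
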