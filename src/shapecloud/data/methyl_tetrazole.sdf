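methyl_tetrazole
     RDKit          3D

 10 10  0  0  0  0  0  0  0  0999 V2000
   -1.3393   -0.1045   -0.4312 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0800   -0.2460   -0.0621 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8603   -1.2964   -0.1983 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.0889   -0.9245    0.2935 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.0687    0.3290    0.7245 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.8186    0.7529    0.5037 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7194   -1.0336   -0.8671 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4698    0.6944   -1.1676 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9462    0.1311    0.4484 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.5581    1.6976    0.7562 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  2  1  0
  1  7  1  0
  1  8  1  0
  1  9  1  0
  6 10  1  0
M  END
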