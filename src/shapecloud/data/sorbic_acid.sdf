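sorbic_acid
     RDKit          3D

 16 15  0  0  0  0  0  0  0  0999 V2000
   -3.1336   -0.4158   -0.7142 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6885   -0.7013   -0.4617 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7737    0.2468   -0.2105 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6195   -0.0547    0.0308 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5341    0.8936    0.2820 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.9546    0.6146    0.5304 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7911    1.4701    0.7592 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.2745   -0.6872    0.4860 O   0  0  0  0  0  0  0  0  0  0  0  0
   -3.4184   -0.7844   -1.7044 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7497   -0.9250    0.0331 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3589    0.6544   -0.6705 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3991   -1.7496   -0.4914 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0756    1.2923   -0.1834 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.9131   -1.1026    0.0019 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2739    1.9455    0.3176 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.2366   -0.6968    0.6687 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  6  8  1  0
  1  9  1  0
  1 10  1  0
  1 11  1  0
  2 12  1  0
  3 13  1  0
  4 14  1  0
  5 15  1  0
  8 16  1  0
M  END
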