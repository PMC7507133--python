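toluene
     RDKit          3D

 15 15  0  0  0  0  0  0  0  0999 V2000
    2.2127   -0.1580   -0.1133 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7202   -0.0504   -0.0121 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0711   -1.2037    0.0577 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4621   -1.1041    0.1202 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0739    0.1479    0.1030 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2955    1.3009    0.0189 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0956    1.2026   -0.0436 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.6988    0.7119    0.3408 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.5127   -0.2230   -1.1637 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.5771   -1.0454    0.4148 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.3921   -2.1876    0.0646 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0682   -2.0041    0.1794 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1567    0.2249    0.1507 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7717    2.2775   -0.0009 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6898    2.1105   -0.1164 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  6  7  2  0
  7  2  1  0
  1  8  1  0
  1  9  1  0
  1 10  1  0
  3 11  1  0
  4 12  1  0
  5 13  1  0
  6 14  1  0
  7 15  1  0
M  END
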