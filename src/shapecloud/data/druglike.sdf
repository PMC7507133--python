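druglike
     RDKit          3D

 56 58  0  0  0  0  0  0  0  0999 V2000
    9.8203    0.6568   -0.5551 C   0  0  0  0  0  0  0  0  0  0  0  0
    9.1717   -0.6325   -0.0751 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.7195   -0.4323    0.2790 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.7203   -0.6229   -0.6854 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.3753   -0.4199   -0.3640 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.0178   -0.0261    0.9314 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5964    0.2031    1.3155 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.3473    1.1121    2.0973 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.6978   -0.6887    0.7583 N   0  0  0  0  0  0  0  0  0  0  0  0
    1.2949   -0.6969    0.9075 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5947   -1.7563    0.3162 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7985   -1.8381    0.4132 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5199   -0.8565    1.1014 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0275   -0.9431    1.2261 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7270    0.2149    0.6505 N   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5206    0.3015   -0.8116 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.7250    0.9001   -1.5680 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.9121    0.0314   -1.4542 N   0  0  0  0  0  0  0  0  0  0  0  0
   -7.1082    0.6999   -1.9977 C   0  0  0  0  0  0  0  0  0  0  0  0
   -8.2605   -0.2706   -2.3156 C   0  0  0  0  0  0  0  0  0  0  0  0
   -9.0448   -0.5563   -1.1615 O   0  0  0  0  0  0  0  0  0  0  0  0
   -6.0920   -0.4501   -0.0677 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1632    0.2020    0.9859 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8170    0.2038    1.6884 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5770    0.2840    1.5903 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.0129    0.1913    1.8901 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.3556   -0.0147    1.5662 C   0  0  0  0  0  0  0  0  0  0  0  0
   10.8706    0.4805   -0.8079 H   0  0  0  0  0  0  0  0  0  0  0  0
    9.3173    1.0467   -1.4465 H   0  0  0  0  0  0  0  0  0  0  0  0
    9.7830    1.4325    0.2177 H   0  0  0  0  0  0  0  0  0  0  0  0
    9.2599   -1.4027   -0.8512 H   0  0  0  0  0  0  0  0  0  0  0  0
    9.7127   -1.0185    0.7977 H   0  0  0  0  0  0  0  0  0  0  0  0
    6.9875   -0.9185   -1.6981 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.6250   -0.5400   -1.1405 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0861   -1.4653    0.2407 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1212   -2.5369   -0.2263 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3154   -2.6728   -0.0544 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2413   -1.0099    2.3015 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3958   -1.8783    0.7839 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6375    0.9217   -1.0045 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3187   -0.6885   -1.2439 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.9321    1.9102   -1.1899 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.4555    0.9995   -2.6262 H   0  0  0  0  0  0  0  0  0  0  0  0
   -7.4474    1.4954   -1.3227 H   0  0  0  0  0  0  0  0  0  0  0  0
   -6.8314    1.1691   -2.9507 H   0  0  0  0  0  0  0  0  0  0  0  0
   -7.8828   -1.2096   -2.7342 H   0  0  0  0  0  0  0  0  0  0  0  0
   -8.9255    0.1885   -3.0548 H   0  0  0  0  0  0  0  0  0  0  0  0
   -9.6989   -1.2244   -1.4278 H   0  0  0  0  0  0  0  0  0  0  0  0
   -5.9019   -1.5304   -0.0750 H   0  0  0  0  0  0  0  0  0  0  0  0
   -7.1199   -0.3232    0.2859 H   0  0  0  0  0  0  0  0  0  0  0  0
   -5.4749    1.2483    1.1076 H   0  0  0  0  0  0  0  0  0  0  0  0
   -5.3401   -0.2602    1.9653 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3581    0.9836    2.2214 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0690    1.1317    2.0565 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.7430    0.5222    2.8911 H   0  0  0  0  0  0  0  0  0  0  0  0
    8.1167    0.1597    2.3240 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  7  9  1  0
  9 10  1  0
 10 11  2  0
 11 12  1  0
 12 13  2  0
 13 14  1  0
 14 15  1  0
 15 16  1  0
 16 17  1  0
 17 18  1  0
 18 19  1  0
 19 20  1  0
 20 21  1  0
 18 22  1  0
 22 23  1  0
 13 24  1  0
 24 25  2  0
  6 26  1  0
 26 27  2  0
 27  3  1  0
 25 10  1  0
 23 15  1  0
  1 28  1  0
  1 29  1  0
  1 30  1  0
  2 31  1  0
  2 32  1  0
  4 33  1  0
  5 34  1  0
  9 35  1  0
 11 36  1  0
 12 37  1  0
 14 38  1  0
 14 39  1  0
 16 40  1  0
 16 41  1  0
 17 42  1  0
 17 43  1  0
 19 44  1  0
 19 45  1  0
 20 46  1  0
 20 47  1  0
 21 48  1  0
 22 49  1  0
 22 50  1  0
 23 51  1  0
 23 52  1  0
 24 53  1  0
 25 54  1  0
 26 55  1  0
 27 56  1  0
M  END
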