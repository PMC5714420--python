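# cobaltmc lead form factor v1
# columns: x_inv_angstrom, F
0.000000e+00,8.200000e+01
5.000000e-02,8.040000e+01
1.000000e-01,7.710000e+01
1.500000e-01,7.290000e+01
2.000000e-01,6.830000e+01
3.000000e-01,5.960000e+01
4.000000e-01,5.240000e+01
5.000000e-01,4.660000e+01
6.000000e-01,4.200000e+01
8.000000e-01,3.520000e+01
1.000000e+00,3.040000e+01
1.500000e+00,2.290000e+01
2.000000e+00,1.850000e+01
3.000000e+00,1.360000e+01
4.000000e+00,1.090000e+01
5.000000e+00,9.050000e+00
6.000000e+00,7.670000e+00
8.000000e+00,5.800000e+00
1.000000e+01,4.600000e+00
1.500000e+01,2.890000e+00
2.000000e+01,2.040000e+00
3.000000e+01,1.170000e+00
4.000000e+01,7.600000e-01
6.000000e+01,3.800000e-01
8.000000e+01,2.200000e-01
1.000000e+02,1.400000e-01
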