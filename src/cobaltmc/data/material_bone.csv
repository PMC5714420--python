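# cobaltmc material table v1
# material: bone
# columns: energy_mev, pe, compton, rayleigh, total (cm^2/g), stopping_power (MeV cm^2/g)
1.000000e-02,2.818124e+01,1.985585e-01,1.302000e-01,2.851000e+01,2.041680e+01
1.500000e-02,8.743559e+00,1.949908e-01,9.345000e-02,9.032000e+00,1.490535e+01
2.000000e-02,3.739062e+00,1.915882e-01,7.035000e-02,4.001000e+00,1.191885e+01
3.000000e-02,1.102365e+00,1.852350e-01,4.340000e-02,1.331000e+00,8.735965e+00
4.000000e-02,4.568897e-01,1.794203e-01,2.919000e-02,6.655000e-01,7.038185e+00
5.000000e-02,2.291917e-01,1.740783e-01,2.093000e-02,4.242000e-01,5.975715e+00
6.000000e-02,1.300020e-01,1.691530e-01,1.564500e-02,3.148000e-01,5.246285e+00
8.000000e-02,5.297628e-02,1.603687e-01,9.555000e-03,2.229000e-01,4.305085e+00
1.000000e-01,2.633321e-02,1.527618e-01,6.405000e-03,1.855000e-01,3.724075e+00
1.500000e-01,7.393522e-03,1.375265e-01,3.080000e-03,1.480000e-01,2.930390e+00
2.000000e-01,3.097383e-03,1.260176e-01,1.785000e-03,1.309000e-01,2.527665e+00
3.000000e-01,8.869365e-04,1.095766e-01,8.365000e-04,1.113000e-01,2.131275e+00
4.000000e-01,4.165597e-04,9.817694e-02,4.865000e-04,9.908000e-02,1.943940e+00
5.000000e-01,2.542140e-04,8.964729e-02,3.185000e-04,9.022000e-02,1.840770e+00
6.000000e-01,1.665528e-04,8.292945e-02,2.240000e-04,8.332000e-02,1.776515e+00
8.000000e-01,1.083235e-04,7.284218e-02,1.295000e-04,7.308000e-02,1.706830e+00
1.000000e+00,9.737294e-05,6.547863e-02,8.400000e-05,6.566000e-02,1.673345e+00
1.250000e+00,1.176415e-04,5.853776e-02,5.460000e-05,5.871000e-02,1.655245e+00
1.330000e+00,1.000000e-08,5.668550e-02,4.830000e-05,5.673381e-02,1.651625e+00
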