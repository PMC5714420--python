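# cobaltmc material table v1
# material: aluminum
# columns: energy_mev, pe, compton, rayleigh, total (cm^2/g), stopping_power (MeV cm^2/g)
1.000000e-02,2.558917e+01,1.858342e-01,4.550000e-01,2.623000e+01,1.787880e+01
1.500000e-02,7.448505e+00,1.824952e-01,3.240000e-01,7.955000e+00,1.305247e+01
2.000000e-02,3.018689e+00,1.793107e-01,2.430000e-01,3.441000e+00,1.043722e+01
3.000000e-02,8.066355e-01,1.733645e-01,1.480000e-01,1.128000e+00,7.650003e+00
4.000000e-02,3.022775e-01,1.679225e-01,9.830000e-02,5.685000e-01,6.163272e+00
5.000000e-02,1.351772e-01,1.629228e-01,7.000000e-02,3.681000e-01,5.232877e+00
6.000000e-02,6.748690e-02,1.583131e-01,5.200000e-02,2.778000e-01,4.594123e+00
8.000000e-02,2.010821e-02,1.500918e-01,3.160000e-02,2.018000e-01,3.769922e+00
1.000000e-01,6.327664e-03,1.429723e-01,2.110000e-02,1.704000e-01,3.261138e+00
1.500000e-01,1.000000e-08,1.287134e-01,1.010000e-02,1.388134e-01,2.566115e+00
2.000000e-01,1.000000e-08,1.179420e-01,5.800000e-03,1.237420e-01,2.213453e+00
3.000000e-01,1.000000e-08,1.025546e-01,2.700000e-03,1.052546e-01,1.866337e+00
4.000000e-01,1.000000e-08,9.188545e-02,1.560000e-03,9.344546e-02,1.702290e+00
5.000000e-01,1.000000e-08,8.390241e-02,1.020000e-03,8.492242e-02,1.611945e+00
6.000000e-01,1.000000e-08,7.761507e-02,7.200000e-04,7.833508e-02,1.555678e+00
8.000000e-01,1.000000e-08,6.817422e-02,4.100000e-04,6.858423e-02,1.494655e+00
1.000000e+00,1.000000e-08,6.128255e-02,2.700000e-04,6.155256e-02,1.465332e+00
1.250000e+00,1.000000e-08,5.478648e-02,1.740000e-04,5.496049e-02,1.449483e+00
1.330000e+00,1.000000e-08,5.305292e-02,1.540000e-04,5.320693e-02,1.446312e+00
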