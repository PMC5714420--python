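# cobaltmc material table v1
# material: lung
# columns: energy_mev, pe, compton, rayleigh, total (cm^2/g), stopping_power (MeV cm^2/g)
1.000000e-02,5.077702e+00,2.140983e-01,3.720000e-02,5.329000e+00,2.249232e+01
1.500000e-02,1.436049e+00,2.102514e-01,2.670000e-02,1.673000e+00,1.642059e+01
2.000000e-02,5.829174e-01,2.065826e-01,2.010000e-02,8.096000e-01,1.313049e+01
3.000000e-02,1.634679e-01,1.997321e-01,1.240000e-02,3.756000e-01,9.624041e+00
4.000000e-02,6.649765e-02,1.934624e-01,8.340000e-03,2.683000e-01,7.753669e+00
5.000000e-02,3.321777e-02,1.877022e-01,5.980000e-03,2.269000e-01,6.583191e+00
6.000000e-02,1.903856e-02,1.823914e-01,4.470000e-03,2.059000e-01,5.779609e+00
8.000000e-02,8.050274e-03,1.729197e-01,2.730000e-03,1.837000e-01,4.742729e+00
1.000000e-01,4.152551e-03,1.647174e-01,1.830000e-03,1.707000e-01,4.102655e+00
1.500000e-01,1.330231e-03,1.482898e-01,8.800000e-04,1.505000e-01,3.228286e+00
2.000000e-01,6.098155e-04,1.358802e-01,5.100000e-04,1.370000e-01,2.784621e+00
3.000000e-01,2.086017e-04,1.181524e-01,2.390000e-04,1.186000e-01,2.347935e+00
4.000000e-01,1.003982e-04,1.058606e-01,1.390000e-04,1.061000e-01,2.141556e+00
5.000000e-01,1.156123e-04,9.666339e-02,9.100000e-05,9.687000e-02,2.027898e+00
6.000000e-01,7.621205e-05,8.941979e-02,6.400000e-05,8.956000e-02,1.957111e+00
8.000000e-01,6.994685e-05,7.854305e-02,3.700000e-05,7.865000e-02,1.880342e+00
1.000000e+00,9.279274e-05,7.060321e-02,2.400000e-05,7.072000e-02,1.843453e+00
1.250000e+00,9.527727e-05,6.311912e-02,1.560000e-05,6.323000e-02,1.823513e+00
1.330000e+00,1.000000e-08,6.112190e-02,1.380000e-05,6.113571e-02,1.819525e+00
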