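# cobaltmc material table v1
# material: air
# columns: energy_mev, pe, compton, rayleigh, total (cm^2/g), stopping_power (MeV cm^2/g)
1.000000e-02,4.891378e+00,1.925377e-01,3.608400e-02,5.120000e+00,2.025888e+01
1.500000e-02,1.399023e+00,1.890782e-01,2.589900e-02,1.614000e+00,1.479006e+01
2.000000e-02,5.726242e-01,1.857788e-01,1.949700e-02,7.779000e-01,1.182666e+01
3.000000e-02,1.621538e-01,1.796182e-01,1.202800e-02,3.538000e-01,8.668394e+00
4.000000e-02,6.643036e-02,1.739798e-01,8.089800e-03,2.485000e-01,6.983746e+00
5.000000e-02,3.339961e-02,1.687998e-01,5.800600e-03,2.080000e-01,5.929494e+00
6.000000e-02,1.914028e-02,1.640238e-01,4.335900e-03,1.875000e-01,5.205706e+00
8.000000e-02,8.045949e-03,1.555060e-01,2.648100e-03,1.662000e-01,4.271786e+00
1.000000e-01,4.195221e-03,1.481297e-01,1.775100e-03,1.541000e-01,3.695270e+00
1.500000e-01,1.390062e-03,1.333563e-01,8.536000e-04,1.356000e-01,2.907724e+00
2.000000e-01,6.088466e-04,1.221965e-01,4.947000e-04,1.233000e-01,2.508114e+00
3.000000e-01,2.142369e-04,1.062539e-01,2.318300e-04,1.067000e-01,2.114790e+00
4.000000e-01,1.551956e-04,9.519997e-02,1.348300e-04,9.549000e-02,1.928904e+00
5.000000e-01,1.027698e-04,8.692896e-02,8.827000e-05,8.712000e-02,1.826532e+00
6.000000e-01,7.309727e-05,8.041482e-02,6.208000e-05,8.055000e-02,1.762774e+00
8.000000e-01,7.068713e-05,7.063342e-02,3.589000e-05,7.074000e-02,1.693628e+00
1.000000e+00,6.356568e-05,6.349315e-02,2.328000e-05,6.358000e-02,1.660402e+00
1.250000e+00,9.211804e-05,5.676275e-02,1.513200e-05,5.687000e-02,1.642442e+00
1.330000e+00,1.000000e-08,5.496666e-02,1.338600e-05,5.498006e-02,1.638850e+00
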