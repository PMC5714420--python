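# cobaltmc material table v1
# material: lead
# columns: energy_mev, pe, compton, rayleigh, total (cm^2/g), stopping_power (MeV cm^2/g)
1.000000e-02,1.159474e+02,1.526409e-01,1.450000e+01,1.306000e+02,1.353600e+01
1.500000e-02,1.015501e+02,1.498982e-01,9.900000e+00,1.116000e+02,9.882000e+00
2.000000e-02,7.901272e+01,1.472825e-01,7.200000e+00,8.636000e+01,7.902000e+00
3.000000e-02,2.607760e+01,1.423985e-01,4.100000e+00,3.032000e+01,5.791800e+00
4.000000e-02,1.153207e+01,1.379285e-01,2.690000e+00,1.436000e+01,4.666200e+00
5.000000e-02,5.977178e+00,1.338218e-01,1.930000e+00,8.041000e+00,3.961800e+00
6.000000e-02,3.430964e+00,1.300355e-01,1.460000e+00,5.021000e+00,3.478200e+00
8.000000e-02,1.370717e+00,1.232827e-01,9.250000e-01,2.419000e+00,2.854200e+00
1.000000e-01,4.791565e+00,1.174349e-01,6.400000e-01,5.549000e+00,2.469000e+00
1.500000e-01,1.574277e+00,1.057228e-01,3.340000e-01,2.014000e+00,1.942800e+00
2.000000e-01,7.166246e-01,9.687543e-02,1.850000e-01,9.985000e-01,1.675800e+00
3.000000e-01,2.508635e-01,8.423645e-02,6.800000e-02,4.031000e-01,1.413000e+00
4.000000e-01,1.168270e-01,7.547305e-02,4.000000e-02,2.323000e-01,1.288800e+00
5.000000e-01,6.598408e-02,6.891592e-02,2.650000e-02,1.614000e-01,1.220400e+00
6.000000e-01,4.204839e-02,6.375161e-02,1.900000e-02,1.248000e-01,1.177800e+00
8.000000e-01,2.170293e-02,5.599707e-02,1.100000e-02,8.870000e-02,1.131600e+00
1.000000e+00,1.348362e-02,5.033638e-02,7.200000e-03,7.102000e-02,1.109400e+00
1.250000e+00,8.959382e-03,4.500062e-02,4.800000e-03,5.876000e-02,1.097400e+00
1.330000e+00,9.093295e-03,4.357671e-02,4.300000e-03,5.697000e-02,1.095000e+00
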