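11
pyridine, idealized planar hexagon placeholder geometry (synthetic; not an optimized structure)
C       0.000000000000     1.390000000000     0.000000000000
C       1.203775311260     0.695000000000     0.000000000000
C      -1.203775311260     0.695000000000     0.000000000000
C       1.203775311260    -0.695000000000     0.000000000000
C      -1.203775311260    -0.695000000000     0.000000000000
N       0.000000000000    -1.390000000000     0.000000000000
H       0.000000000000     2.470000000000     0.000000000000
H       2.139082747348     1.235000000000     0.000000000000
H      -2.139082747348     1.235000000000     0.000000000000
H       2.139082747348    -1.235000000000     0.000000000000
H      -2.139082747348    -1.235000000000     0.000000000000
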