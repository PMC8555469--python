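name,x,y,z
F3,-0.545007,0.673028,0.500000
Fz,0.000000,0.719340,0.694658
F4,0.545007,0.673028,0.500000
FC1,-0.374710,0.374710,0.848048
FC5,-0.887888,0.340828,0.309017
FC2,0.374710,0.374710,0.848048
FC6,0.887888,0.340828,0.309017
C3,-0.719340,-0.000000,0.694658
Cz,0.000000,0.000000,1.000000
C4,0.719340,0.000000,0.694658
CP1,-0.374710,-0.374710,0.848048
CP5,-0.887888,-0.340828,0.309017
CP2,0.374710,-0.374710,0.848048
CP6,0.887888,-0.340828,0.309017
T7,-0.999391,-0.000000,-0.034899
T8,0.999391,0.000000,-0.034899
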