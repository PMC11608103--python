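# Constants for the nitrate example network. All three reactions are
# kinetic; the only entries needed are placeholders for completeness of the
# signatures (no equilibrium reactions are used beyond defaults).
soilN(s) = NO3- : logK=0.0
NO3- = PlantN(s) : logK=0.0
NO3- = N2O(g) : logK=0.0
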