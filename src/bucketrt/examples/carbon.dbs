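# Thermodynamic constants for the carbon example network.
# Carbonate dissolution is written with its reported non-integer
# stoichiometry, inorganic carbon carried on HCO3-.
CO2(aq) + H2O = HCO3- + H+ : logK=-6.35
HCO3- = CO3-- + H+ : logK=-10.33
H2O = H+ + OH- : logK=-14.0
>X + DOC = >XDOC : logK=-1.00
CarbonateSZ(s) = 1.1 Ca++ + 0.5 HCO3- : logK=-7.40, logk=-9.19, ssa=1.0
CarbonateDZ(s) = 0.9 Ca++ + 0.7 HCO3- : logK=-7.40, logk=-9.19, ssa=0.0008
CO2(g) = CO2(aq) : logK=-3.20, logk=-13.10
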