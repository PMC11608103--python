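# Carbon cycling network: soil respiration, DOC sorption, carbonate
# weathering, and CO2 gas-aqueous exchange.
#
# Five primary species (DOC, HCO3-, Ca++, H+, sorption sites >X) and four
# secondaries (CO3--, CO2(aq), OH-, >XDOC). Dissolved inorganic carbon is a
# reporting aggregate CO2(aq) + HCO3- + CO3--, carried on HCO3- in reaction
# stoichiometry.
#
# substrate_density (g/m^2 catchment) converts the specific surface area
# (m^2/g) into the constant per-reaction area term; values are
# order-of-magnitude estimates for a forested soil column.

[species]
primary = ["DOC", "HCO3-", "Ca++", "H+"]
sorption_site = [">X"]
secondary = ["CO3--", "CO2(aq)", "OH-"]
sorbed = [">XDOC"]
solid = ["OC(s)", "Roots(s)", "OCDZ(s)", "CarbonateSZ(s)", "CarbonateDZ(s)"]
gas = ["CO2(g)"]

[secondary_reactions]
"CO2(aq)" = "CO2(aq) + H2O = HCO3- + H+"
"CO3--" = "HCO3- = CO3-- + H+"
"OH-" = "H2O = H+ + OH-"
">XDOC" = { signature = ">X + DOC = >XDOC", zones = ["SZ"] }

[[kinetics.SZ]]
name = "Resp_SZ"
signature = "OC(s) + Roots(s) = 0.6 DOC + 0.55 HCO3-"
rate = "monod"
log10_k = -10.2
ssa = 0.10
substrate = "OC(s)"
substrate_density = 200.0
q10 = 2.3
n = 0.8
swc = 0.7
alpha_beta = 0.0
monod = { "OC(s)" = 6e-6 }

[[kinetics.SZ]]
name = "Carbonate_SZ"
signature = "CarbonateSZ(s) = 1.1 Ca++ + 0.5 HCO3-"
rate = "tst"
log10_k = -9.19
ssa = 1.0
substrate = "CarbonateSZ(s)"
substrate_density = 0.1
q10 = 1.0
n = 1.0
swc = 1.0
alpha_beta = 0.0

[[kinetics.SZ]]
name = "CO2_exchange_SZ"
signature = "CO2(g) = CO2(aq)"
rate = "tst"
log10_k = -13.10
ssa = 0.01
substrate = "CO2(g)"
substrate_density = 2e7
q10 = 3.0
n = 2.0
swc = 0.7
alpha_beta = 0.0

[[kinetics.DZ]]
name = "Resp_DZ"
signature = "OCDZ(s) + DOC = 0.7 HCO3-"
rate = "monod"
log10_k = -9.2
ssa = 0.07
substrate = "OCDZ(s)"
substrate_density = 25000.0
q10 = 1.0
n = 1.2
swc = 0.6
alpha_beta = 0.0
monod = { "DOC" = 5e-3 }

[[kinetics.DZ]]
name = "Carbonate_DZ"
signature = "CarbonateDZ(s) = 0.9 Ca++ + 0.7 HCO3-"
rate = "tst"
log10_k = -9.19
ssa = 0.0008
substrate = "CarbonateDZ(s)"
substrate_density = 1250.0
q10 = 3.0
n = 0.9
swc = 1.0
alpha_beta = 0.0

[[kinetics.DZ]]
name = "CO2_exchange_DZ"
signature = "CO2(g) = CO2(aq)"
rate = "tst"
log10_k = -13.10
ssa = 0.007
substrate = "CO2(g)"
substrate_density = 2e7
q10 = 1.5
n = 0.0
swc = 0.7
alpha_beta = 0.0
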