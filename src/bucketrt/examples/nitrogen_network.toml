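# Nitrate network: soil N leaching (net nitrate production), plant uptake
# (zero-order removal), and denitrification (Monod in nitrate). Three kinetic
# reactions per subsurface zone, no equilibrium reactions.
#
# The soil-moisture response uses swc = 1 throughout (rates rise with
# wetness up to saturation); the exponent n varies by reaction and is 0
# (disabled) in the deep zone.

[species]
primary = ["NO3-"]
solid = ["soilN(s)", "PlantN(s)"]
gas = ["N2O(g)"]

[[kinetics.SZ]]
name = "NLeaching_SZ"
signature = "soilN(s) = NO3-"
rate = "monod"
log10_k = -15.0
ssa = 5.5
substrate = "soilN(s)"
substrate_density = 2e6
q10 = 2.0
n = 1.7
swc = 1.0
alpha_beta = 0.0
monod = { "soilN(s)" = 6e-4 }

[[kinetics.SZ]]
name = "PlantUptake_SZ"
signature = "NO3- = PlantN(s)"
rate = "monod"
log10_k = -13.4
ssa = 3.0
substrate = "PlantN(s)"
substrate_density = 6e4
q10 = 1.5
n = 1.25
swc = 1.0
alpha_beta = 0.0

[[kinetics.SZ]]
name = "Denitrification_SZ"
signature = "NO3- = N2O(g)"
rate = "monod"
log10_k = -12.8
ssa = 1e-6
substrate = "N2O(g)"
substrate_density = 1e9
q10 = 1.0
n = 0.0
swc = 1.0
alpha_beta = 0.0
monod = { "NO3-" = 1e-6 }

[[kinetics.DZ]]
name = "NLeaching_DZ"
signature = "soilN(s) = NO3-"
rate = "monod"
log10_k = -15.0
ssa = 1e-4
substrate = "soilN(s)"
substrate_density = 2e6
q10 = 1.0
n = 0.0
swc = 1.0
alpha_beta = 0.0
monod = { "soilN(s)" = 6e-4 }

[[kinetics.DZ]]
name = "PlantUptake_DZ"
signature = "NO3- = PlantN(s)"
rate = "monod"
log10_k = -13.4
ssa = 1e-4
substrate = "PlantN(s)"
substrate_density = 1.2e5
q10 = 2.5
n = 0.0
swc = 1.0
alpha_beta = 0.0

[[kinetics.DZ]]
name = "Denitrification_DZ"
signature = "NO3- = N2O(g)"
rate = "monod"
log10_k = -12.8
ssa = 3e-4
substrate = "N2O(g)"
substrate_density = 1e9
q10 = 1.5
n = 0.0
swc = 1.0
alpha_beta = 0.0
monod = { "NO3-" = 1e-6 }
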