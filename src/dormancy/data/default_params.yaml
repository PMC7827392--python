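# Default model constants for the tumor-immune dormancy ODE system.
# Units: cell counts in cells, time in days, rates in day^-1 or cell^-1 day^-1.
# Flat keys; scientific notation is accepted and coerced to float on load.

# Tumor growth (Gompertz)
a1: 0.038        # proliferative (4T1) growth rate, day^-1
a2: 0.0174       # quiescent (MR20) growth rate, day^-1
Cmax: 1.0e+9     # maximum tumor size (carrying capacity), cells

# Immune predation of tumor cells (mass action)
alpha: 0.3       # NK-cytotoxicity proportion coefficient (dimensionless)
# b1 and r1 are derived as alpha*b2 and alpha*r2 when omitted.
b2: 5.2e-8       # NK kill rate on quiescent cells, cell^-1 day^-1
eta1: 2.1e-8     # CD8+ T kill rate on proliferative cells, cell^-1 day^-1
eta2: 2.8e-7     # CD8+ T kill rate on quiescent cells, cell^-1 day^-1

# NK compartment
s: 1.3e+4        # constant NK source, cells day^-1
g: 2.5e-2        # maximum NK recruitment rate, day^-1
h: 2.02e+7       # NK recruitment-curve steepness, cell^2
f: 4.12e-2       # NK death rate, day^-1
p: 1.8e-8        # NK inactivation rate by tumor cells, cell^-1 day^-1

# CD8+ T compartment
r2: 1.2e-7       # CTL stimulation coefficient (quiescent tumor-NK), cell^-1 day^-1
j: 0.1           # maximum CTL recruitment rate, day^-1
k: 2.02e+7       # CTL recruitment-curve steepness, cell^2
m: 2.0e-2        # CTL death rate, day^-1
u1: 2.1e-8       # CTL inactivation rate by proliferative cells, cell^-1 day^-1
u2: 1.7e-12      # CTL inactivation rate by quiescent cells, cell^-1 day^-1

# Default initial state (the quiescent dormancy scenario)
Cp0: 0.0         # initial proliferative cells
Cq0: 5.0e+4      # initial quiescent cells
N0: 2.5e+5       # initial NK cells
T0: 5.2e+5       # initial CD8+ T cells
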