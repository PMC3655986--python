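# Best-fit Nav1.5 rate-law parameters (shared by the 8- and 12-state models).
# Exponential laws: rate = k * exp(V/n), k in 1/ms, n in mV.
# rho1 is sigmoid: rho1(V) = g / (1 + exp(-(V + a)/f)), g in 1/ms, a and f in mV.
# c is a dimensionless row-to-row scale factor.
alpha1: {k: 9.435, n: 39.70}
alpha2: {k: 441.1, n: 6.593}
alpha3: {k: 11.17, n: 11.64}
beta1: {k: 0.000037, n: -7.770}
beta2: {k: 0.2241, n: -21.13}
phi1: {k: 0.000020, n: -13.07}
phi2: {k: 0.000302, n: -47.08}
phi3: {k: 0.000230, n: -57.21}
rho1: {g: 0.01296, a: 85.62, f: 15.64}
rho2: {k: 1.823, n: 92.78}
rho3: {k: 0.000315, n: 965.2}
c: 2.146
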