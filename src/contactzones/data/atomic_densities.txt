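# Spherically averaged atomic electron densities as sums of exponentials:
#     rho_elem(r) = sum_k c_k * exp(-z_k * r)     [rho in e/A^3, r in A]
#
# Provenance: least-squares fits (performed for this package) to
# Slater-type-orbital atomic densities built from Clementi-Raimondi
# effective exponents, with each shell normalized to its occupancy.
# The fit weights the exterior density band (1e-6 to 0.5 e/A^3) that
# controls interface geometry and the solvent-exposure cutoff.
# Coefficients are rescaled so that 4*pi * integral rho r^2 dr equals the
# element's electron count exactly.
#
# Accuracy note: a sum of decaying exponentials has a log-convex radial
# profile and cannot reproduce the log-concave valence-shell shoulder of
# r^2-weighted Slater shells; deviations from the STO reference reach
# ~+/-50% in the exterior band and ~2x near 0.3-0.5 A inside atoms.
# This is a property of the chosen analytic form.  Hydrogen's 1s density
# is a single exact exponential.
#
# element   coefficient (e/A^3)   exponent (1/A)
H 2.1480615850e+00 3.7794522493
C 6.4102753756e+02 29.4562000000
C 2.5313396386e+01 4.9115090437
N 9.2640394113e+02 40.0154021658
N 5.9475410863e+01 6.0842923996
O 1.3769096359e+03 53.4625956207
O 1.1396717237e+02 7.1691384483
P 1.1482747816e+04 70.0000000000
P 7.9377896016e+02 18.5586578842
P 3.7237092610e+01 4.3931963058
S 9.9481630867e+03 70.0000000000
S 6.7401768538e+02 22.5621610617
S 7.1270987270e+01 5.0636651614
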