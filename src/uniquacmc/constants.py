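"""Physical constants shared across the package.

Energies are J/mol throughout the public API; the inference machinery
works with U/R in Kelvin internally for numerical conditioning.
"""

#: Gas constant, J/(mol K) (CODATA 2018 exact value).
R_GAS = 8.314462618

#: Lattice coordination number of the quasi-chemical lattice. The canonical
#: UNIQUAC choice; not a user knob.
Z_COORDINATION = 10.0

#: Boltzmann-factor exponents are clipped to +/- this value before
#: exponentiation, so optimizer excursions cannot overflow exp().
TAU_EXPONENT_CLIP = 500.0
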