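"""Physical constants (CODATA 2018, 9 significant digits)."""

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.85418781e-12

#: Boltzmann constant, J/K (exact in the 2019 SI).
K_BOLTZMANN = 1.38064900e-23

#: Avogadro constant, 1/mol (exact in the 2019 SI).
N_AVOGADRO = 6.02214076e23

#: Ångström in metres.
ANGSTROM = 1.0e-10
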