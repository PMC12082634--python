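"""Physical constants in the package's unit system (nm, ns, K, kJ/mol)."""

#: Gas constant, kJ/(mol K)
R_KJ = 8.314462618e-3

#: Boltzmann constant, J/K
K_B = 1.380649e-23

#: Planck constant, J s
PLANCK_H = 6.62607015e-34
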