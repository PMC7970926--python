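"""Physical constants (CODATA 2018) used by the Eyring kinetics."""

#: Boltzmann constant, J/K (exact since the 2019 SI redefinition).
K_B = 1.380649e-23

#: Planck constant, J·s (exact).
H_P = 6.62607015e-34

#: Offset between the Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15
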