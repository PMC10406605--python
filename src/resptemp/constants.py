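"""Physical constants shared across the package."""

#: Boltzmann constant in eV per kelvin.
K_B = 8.617333262e-5

#: Reference temperature (10 degC) for baseline respiration, kelvin.
T_REF = 283.15

#: Temperature increment used in the apparent-Q10 conversion, kelvin.
DT10 = 10.0

#: Units used on gridded fields.
UNITS_TEMPERATURE = "K"
UNITS_FLUX = "umol m-2 s-1"
UNITS_SW = "W m-2"
UNITS_PPM = "ppm"
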