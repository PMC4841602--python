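"""Physical constants and unit conventions.

Internal units throughout the package:

==============  ==========
quantity        unit
==============  ==========
time            ms
voltage         mV
unitary conductance  pS
unit current    pA (per channel); pA/pF for density-factor species
current density pA/pF
capacitance     pF
[Ca2+]_i        nM
[ATP]_o         uM
other ion concentrations  mM
==============  ==========

With densities in channels/pF the membrane equation integrates in
per-capacitance form: 1 pA/pF == 1 mV/ms.
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)
BODY_TEMPERATURE = 310.15  # K


def thermal_voltage(temperature: float = BODY_TEMPERATURE) -> float:
    """RT/F in mV."""
    return GAS_CONSTANT * temperature / FARADAY * 1e3
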