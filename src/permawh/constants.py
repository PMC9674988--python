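"""Physical constants and unit conversions.

The simulation core works in kJ mol^-1 / nm / ps throughout; conversion to
cm h^-1 happens only at the permeability reporting boundary.
"""

#: Boltzmann constant in kJ mol^-1 K^-1 (i.e. the molar gas constant).
KB = 0.008314462618

#: Default simulation temperature in K.
DEFAULT_TEMPERATURE = 305.15

#: 1 nm ps^-1 expressed in cm h^-1 (1e-7 cm per nm, 3.6e15 ps per h).
NM_PER_PS_TO_CM_PER_H = 3.6e8

#: 1 ps nm^-1 of permeation resistance expressed in h cm^-1.
PS_PER_NM_TO_H_PER_CM = 1.0 / NM_PER_PS_TO_CM_PER_H
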