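"""Unit conventions and the few conversion constants used across the package.

All lengths and interaction coefficients are stored per millimetre (the native
units of the tissue table and the stereotactic frame); fluence rate is reported
per cm^2 (mW/cm^2) and fluence in J/cm^2, matching the therapeutic threshold
convention.  Every mm^2 -> cm^2 and mW*s -> J conversion in the package goes
through these constants.
"""

#: 1 mm^-2 expressed in cm^-2 (fluence-rate area conversion).
MM2_PER_CM2 = 100.0

#: mW * s per J (1 mW/cm^2 sustained for 1000 s delivers 1 J/cm^2).
MW_S_PER_J = 1000.0

#: mm per cm (linear source power is quoted per cm of diffuser).
MM_PER_CM = 10.0
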