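"""Monoisotopic mass constants (unified atomic mass scale, ¹²C = 12 exactly)."""

MASS_C = 12.0
MASS_H = 1.0078250319
MASS_N = 14.0030740052
MASS_O = 15.9949146221
MASS_S = 31.97207069

#: Mass of a proton, Da; [M-H]⁻ neutral mass = m/z + MASS_PROTON.
MASS_PROTON = 1.00727646

ELEMENT_MASSES = (MASS_C, MASS_H, MASS_N, MASS_O, MASS_S)
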