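"""Physical constants.

Internal arithmetic is carried out in (elementary charge)^2 / Å units; the
Coulomb constant converts to kcal/mol once, at the end of a calculation.
"""

#: kcal Å / (mol e^2)
COULOMB_CONSTANT = 332.0637141
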