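"""Physical constants shared across the package."""

#: molar gas constant in kJ mol^-1 K^-1 (the titration ratio R is unrelated)
GAS_R_KJ: float = 8.314462618e-3

#: thermal energy RT at 300 K, kJ/mol
RT_300K: float = GAS_R_KJ * 300.0
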