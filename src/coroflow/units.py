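"""Unit conversion constants.

All public interfaces use clinical units (mm, mmHg, mL/min, g); the solver
works in SI internally.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

# 1 mL/min = 1e-6 m^3 / 60 s
MLMIN_TO_M3S = 1.0e-6 / 60.0
M3S_TO_MLMIN = 1.0 / MLMIN_TO_M3S

MM_TO_M = 1.0e-3
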