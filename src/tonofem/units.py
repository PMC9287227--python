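"""Unit conventions.

The package works in a millimetre-Newton-MPa system throughout:
lengths in mm, forces in N, moduli and stresses in MPa (N/mm^2).
Intraocular pressure is specified clinically in mmHg and converted with the
metrological definition of the millimetre of mercury.
"""

#: 1 mmHg in MPa (133.322387415 Pa).
MMHG_TO_MPA = 133.322387415e-6

#: 1 mmHg in kPa, convenience for reporting.
MMHG_TO_KPA = 133.322387415e-3


def mmhg_to_mpa(iop_mmhg: float) -> float:
    """Convert an intraocular pressure in mmHg to MPa."""
    return iop_mmhg * MMHG_TO_MPA
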