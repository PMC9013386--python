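"""Unit conventions and physical constants.

User-facing quantities follow lab conventions: lengths in micrometres,
field amplitudes in oersted, frequencies in hertz.  All field/energy/force
arithmetic is done internally in SI.  The two conversion constants below are
the only place the CGS-SI bridge appears.
"""

import numpy as np

#: vacuum permeability, T*m/A
MU0 = 4.0e-7 * np.pi

#: 1 Oe = 1e3/(4*pi) A/m
OE_TO_AM = 1.0e3 / (4.0 * np.pi)

#: metres per micrometre
UM = 1.0e-6

#: Boltzmann constant, J/K
KB = 1.380649e-23


def oe_to_am(h_oe):
    """Convert a field amplitude (or array) from oersted to A/m."""
    return np.asarray(h_oe, dtype=float) * OE_TO_AM


def am_to_oe(h_am):
    """Convert a field amplitude (or array) from A/m to oersted."""
    return np.asarray(h_am, dtype=float) / OE_TO_AM
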