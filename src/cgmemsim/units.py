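"""Internal unit system.

Lengths in nm, time in ps, energy in kJ/mol, mass in amu, angles in
radians.  These units are mutually consistent: 1 amu nm^2/ps^2 equals
exactly 1 kJ/mol, so kinetic energy, forces and the integrator need no
conversion factors.  Temperatures are Kelvin, pressures atmospheres.
"""

import math

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083145

#: 1 atm expressed in kJ/mol/nm^3 (for the barostat virial).
ATM = 0.0610194

#: 2^(1/6), distance of the Lennard-Jones minimum in units of sigma.
RMIN_FACTOR = 2.0 ** (1.0 / 6.0)


def deg2rad(x: float) -> float:
    return x * math.pi / 180.0


def rad2deg(x: float) -> float:
    return x * 180.0 / math.pi
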