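"""Physical constants and the package's internal unit system.

Internal units: lengths in nm, magnetic moments in J/T, fields in mT,
temperatures in K, and energies in units of kB*T at the reference
temperature ``T_REF`` = 300 K ("room temperature").  Working in thermal
units keeps every energy the Metropolis rule sees of order 1-100 and
avoids pushing SI joule values (~1e-19) through repeated arithmetic.
"""

import math

#: Boltzmann constant, J/K (2019 SI exact value).
KB = 1.380649e-23

#: Reference temperature for the thermal energy unit, K.
T_REF = 300.0

#: One energy unit, in joules: kB * 300 K.
KBT_REF = KB * T_REF

#: Vacuum permeability over 4*pi, N/A^2.
MU0_OVER_4PI = 1.0e-7

#: Dipole-dipole prefactor for moments in J/T and separations in nm,
#: yielding energies in kBT at T_REF:
#: E = -DIPOLE_PREF * mi*mj/r_nm^3 * (3 (mi_hat.r_hat)(mj_hat.r_hat) - mi_hat.mj_hat)
DIPOLE_PREF = MU0_OVER_4PI * 1.0e27 / KBT_REF

#: Zeeman prefactor for moments in J/T and fields in mT, energies in
#: kBT at T_REF:  E = -FIELD_PREF * m * B_mT * cos(angle)
FIELD_PREF = 1.0e-3 / KBT_REF

DEG = math.pi / 180.0


def moment_from_radius(radius_nm: float, msat: float) -> float:
    """Permanent dipole moment of a uniformly magnetised sphere.

    ``m = Msat * (4/3) pi R^3`` with ``Msat`` in J m^-3 T^-1 and the
    radius in nm; returns J/T.  For magnetite (Msat = 0.48e6) and
    R = 20 nm this gives 1.61e-17 J/T.
    """
    if radius_nm < 0:
        raise ValueError(f"radius must be non-negative, got {radius_nm}")
    r_m = radius_nm * 1.0e-9
    return msat * (4.0 / 3.0) * math.pi * r_m**3
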