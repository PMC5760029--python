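"""Closed-form two-particle energetics and the critical unbinding angle.

When the external field is rotated away from the filament by an angle
theta, the torque on a tethered particle pulls its linker from the rest
length l0 to a stretched length l(theta).  Comparing the bound energy
(Zeeman + dipole-dipole + elastic + binding) with the unbound one
(Zeeman + dipole-dipole) for a particle whose moment is parallel to its
neighbour's and aligned with the field gives a closed-form criterion:
the particle unbinds once the elastic energy exceeds the binding
magnitude |Eb|, i.e. beyond the angle where

    cos(theta) = a/(2b) + b/(2a) - (sqrt(2|Eb|/kl) + l0)^2 / (2ab),

with lever arms a = R + d/2 and b = a + l0.  With R = 20 nm, d = 10 nm,
l0 = 5 nm, kl = 0.106 kBT/nm^2 and |Eb| = 4 kBT this threshold is ~27
degrees.  These closed forms serve as independent oracles for the Monte
Carlo simulator.

Two algebraically different routes to the stretched length are
available: the published cosine expression (``form="printed"``,
l^2 = a^2 + b^2 + 2 l0 a cos(theta)) and a law-of-cosines rederivation
from the lever-arm geometry (``form="law_of_cosines"``,
l^2 = a^2 + b^2 - 2ab cos(theta), which satisfies l(0) = l0).  Both
yield the same threshold-angle inequality and hence the same critical
angle; the rederived form is used wherever an explicit l(theta) is
needed, because it is the geometrically consistent one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DIPOLE_PREF, FIELD_PREF
from .params import ModelParams


@dataclass(frozen=True)
class TwoParticleGeometry:
    """Lever-arm geometry of one tethered particle next to a fixed one.

    a = R + d/2 is the distance from the filament to the pivoting
    contact point, b = a + l0 the unstretched distance to the linker
    anchor on the particle surface.
    """

    particle_radius: float      # R, nm
    membrane_gap: float         # d, nm
    linker_rest_length: float   # l0, nm

    def __post_init__(self) -> None:
        if self.particle_radius <= 0 or self.membrane_gap < 0 \
                or self.linker_rest_length < 0:
            raise ValueError("invalid two-particle geometry")

    @property
    def a(self) -> float:
        return self.particle_radius + self.membrane_gap / 2.0

    @property
    def b(self) -> float:
        return self.a + self.linker_rest_length

    @classmethod
    def from_params(cls, params: ModelParams) -> "TwoParticleGeometry":
        return cls(params.particle_radius, params.membrane_gap,
                   params.linker_rest_length)


def stretched_linker_length(geom: TwoParticleGeometry, theta_deg: float) -> float:
    """Linker length l(theta) from the law-of-cosines geometry, nm.

    l(0) = l0 (relaxed) and l grows monotonically as the field angle
    pulls the anchor around the pivot.
    """
    a, b = geom.a, geom.b
    c = math.cos(math.radians(theta_deg))
    return math.sqrt(max(0.0, a * a + b * b - 2.0 * a * b * c))


def _threshold_cosine(geom: TwoParticleGeometry, params: ModelParams) -> float:
    """Right-hand side of the threshold inequality for cos(theta)."""
    a, b = geom.a, geom.b
    s = math.sqrt(2.0 * params.binding_energy / params.linker_stiffness)
    return (a / (2.0 * b) + b / (2.0 * a)
            - (s + params.linker_rest_length) ** 2 / (2.0 * a * b))


def critical_unbinding_angle(params: ModelParams, form: str = "printed") -> float:
    """Smallest field angle (degrees) beyond which a tethered particle's
    bound state is unfavourable and the linker breaks.

    Returns 0 when binding is unfavourable at any tilt (e.g. |Eb| -> 0)
    and 180 when no tilt can break the linker.  Both ``form`` choices
    evaluate the same cosine threshold; see the module docstring.
    """
    if params.linker_stiffness <= 0:
        raise ValueError("linker_stiffness must be > 0")
    if form not in ("printed", "law_of_cosines"):
        raise ValueError(f"unknown form {form!r}")
    geom = TwoParticleGeometry.from_params(params)
    rhs = _threshold_cosine(geom, params)
    if rhs >= 1.0:
        return 0.0
    if rhs <= -1.0:
        return 180.0
    return math.degrees(math.acos(rhs))


def bound_unbound_energies(geom: TwoParticleGeometry, params: ModelParams,
                           theta_deg: float) -> tuple[float, float]:
    """(E_bound, E_unbound) of the tethered particle at field angle
    theta, kBT at 300 K.

    Both moments are taken parallel and aligned with the field; the
    neighbouring particle only provides the dipole-dipole interaction,
    which therefore cancels in the difference, as does the Zeeman term:
    E_bound - E_unbound = elastic(l(theta)) - |Eb|.
    """
    m = params.dipole_moment
    dn = 2.0 * geom.particle_radius + geom.membrane_gap
    th = math.radians(theta_deg)
    # pair separated along the filament; both moments at theta to it
    e_dd = -DIPOLE_PREF * m * m * (3.0 * math.cos(th) ** 2 - 1.0) / dn**3
    e_field = -FIELD_PREF * m * params.field_mT  # moment aligned with B
    l = stretched_linker_length(geom, theta_deg)
    ext = max(0.0, l - params.linker_rest_length)
    e_el = 0.5 * params.linker_stiffness * ext * ext
    e_unbound = e_dd + e_field
    e_bound = e_unbound + e_el - params.binding_energy
    return e_bound, e_unbound


def contact_bond_energy(params: ModelParams) -> float:
    """Dipole-dipole energy of a head-to-tail co-axial pair at contact
    separation d_n, kBT at 300 K (about -100 kBT for the defaults)."""
    m = params.dipole_moment
    return -2.0 * DIPOLE_PREF * m * m / params.contact_distance ** 3
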