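"""Model parameters for the tethered dipolar-sphere model.

A magnetosome is modelled as a hard magnetic sphere (radius ``R``,
permanent moment ``m``) surrounded by a membrane of thickness ``d/2``,
elastically tethered to a rigid filament running along the axis of a
cylindrical cell.  All defaults follow the magnetite/Magnetospirillum
parameterisation: R = 20 nm, membrane gap d = 10 nm (contact distance
d_n = 2R + d = 50 nm), saturation magnetisation 0.48e6 J m^-3 T^-1,
linker rest length 5 nm, linker stiffness 0.106 kBT/nm^2 and a binding
energy of 2 kBT.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

from .constants import T_REF, moment_from_radius


@dataclass
class ModelParams:
    """All physical constants and model parameters of a run.

    Lengths are nm, energies kBT at 300 K, fields mT, angles degrees.
    """

    particle_radius: float = 20.0       # R, nm
    membrane_gap: float = 10.0          # d, nm (two membranes between crystals)
    msat: float = 0.48e6                # saturation magnetisation, J m^-3 T^-1
    dipole_moment: float | None = None  # J/T; derived from R and msat if None
    linker_rest_length: float = 5.0     # l0, nm
    linker_stiffness: float = 0.106     # kl, kBT nm^-2
    binding_energy: float = 2.0         # |Eb|, kBT (applied as -|Eb| when bound)
    temperature: float = T_REF          # K
    field_mT: float = 0.0               # |B|, mT
    field_angle_deg: float = 0.0        # theta_B from the filament (+x), degrees
    n_particles: int = 20
    cylinder_radius: float = 250.0      # nm
    cylinder_length: float = 2000.0     # nm
    max_rotation_deg: float = 5.0       # moment-move half-range, per angle

    def __post_init__(self) -> None:
        if self.particle_radius <= 0:
            raise ValueError("particle_radius must be > 0")
        if self.membrane_gap < 0:
            raise ValueError("membrane_gap must be >= 0")
        if self.linker_rest_length < 0:
            raise ValueError("linker_rest_length must be >= 0")
        if self.linker_stiffness < 0:
            raise ValueError("linker_stiffness must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.field_mT < 0:
            raise ValueError("field_mT must be >= 0")
        if not 0.0 <= self.field_angle_deg <= 180.0:
            raise ValueError("field_angle_deg must lie in [0, 180]")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.cylinder_radius <= 0 or self.cylinder_length <= 0:
            raise ValueError("cylinder dimensions must be > 0")
        if self.dipole_moment is None:
            self.dipole_moment = moment_from_radius(self.particle_radius, self.msat)
        if self.dipole_moment <= 0:
            raise ValueError("dipole_moment must be > 0")

    @property
    def contact_distance(self) -> float:
        """Minimal centre-centre distance d_n = 2R + d for equal spheres, nm."""
        return 2.0 * self.particle_radius + self.membrane_gap

    def pair_contact_distance(self, r_i: float, r_j: float) -> float:
        """Contact distance R_i + R_j + d for a (possibly unequal) pair.

        The gap d accounts for the two membranes and is independent of
        crystal size.
        """
        return r_i + r_j + self.membrane_gap

    def field_vector(self) -> tuple[float, float, float]:
        """Field vector in mT; lies in the x-y plane at field_angle_deg
        from the filament axis (+x)."""
        th = math.radians(self.field_angle_deg)
        return (self.field_mT * math.cos(th), self.field_mT * math.sin(th), 0.0)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)
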