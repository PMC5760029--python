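"""System and per-particle state containers.

The canonical container is :class:`SystemState`, a struct-of-arrays
(positions, moment directions, radii, bound flags) chosen so the Monte
Carlo kernels can operate on contiguous numpy buffers.  The filament is
an implicit line along +x through the origin; the cylindrical box is
centred on it.  :class:`ParticleState` is a convenience single-particle
view used by the pairwise energy functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import T_REF


@dataclass
class ParticleState:
    """One hard magnetic sphere.

    position in nm (cell frame, filament along +x through the origin),
    moment_direction a unit vector, moment_magnitude in J/T.
    """

    position: np.ndarray
    moment_direction: np.ndarray
    radius: float
    moment_magnitude: float
    bound: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.moment_direction = np.asarray(self.moment_direction, dtype=float)
        norm = float(np.linalg.norm(self.moment_direction))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0.0:
                raise ValueError("moment_direction must be non-zero")
            self.moment_direction = self.moment_direction / norm
        if self.moment_magnitude <= 0:
            raise ValueError("moment_magnitude must be > 0")

    @property
    def moment(self) -> np.ndarray:
        """Full moment vector m * m_hat, J/T."""
        return self.moment_magnitude * self.moment_direction


@dataclass
class SystemState:
    """Positions, moments and binding flags of all N particles.

    ``field_mT`` is the external field vector in mT (in the x-y plane
    for the standard protocols); ``temperature`` in K.  Energy caches
    live in the engine, not here: the state is plain data.
    """

    positions: np.ndarray          # (N, 3) nm
    moment_dirs: np.ndarray        # (N, 3) unit vectors
    moment_mags: np.ndarray        # (N,) J/T
    radii: np.ndarray              # (N,) nm
    bound: np.ndarray              # (N,) bool
    field_mT: np.ndarray = field(default_factory=lambda: np.zeros(3))
    temperature: float = T_REF

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.moment_dirs = np.ascontiguousarray(self.moment_dirs, dtype=np.float64)
        self.moment_mags = np.ascontiguousarray(self.moment_mags, dtype=np.float64)
        self.radii = np.ascontiguousarray(self.radii, dtype=np.float64)
        self.bound = np.ascontiguousarray(self.bound, dtype=np.bool_)
        self.field_mT = np.asarray(self.field_mT, dtype=np.float64)
        n = len(self.positions)
        for name in ("moment_dirs", "moment_mags", "radii", "bound"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match positions ({n})")
        norms = np.linalg.norm(self.moment_dirs, axis=1)
        if n and np.max(np.abs(norms - 1.0)) > 1e-9:
            self.moment_dirs = self.moment_dirs / norms[:, None]

    @property
    def n(self) -> int:
        return len(self.positions)

    def particle(self, i: int) -> ParticleState:
        return ParticleState(
            position=self.positions[i].copy(),
            moment_direction=self.moment_dirs[i].copy(),
            radius=float(self.radii[i]),
            moment_magnitude=float(self.moment_mags[i]),
            bound=bool(self.bound[i]),
        )

    def moments(self) -> np.ndarray:
        """(N, 3) array of full moment vectors, J/T."""
        return self.moment_mags[:, None] * self.moment_dirs

    def net_moment(self) -> np.ndarray:
        return self.moments().sum(axis=0)

    def bound_count(self) -> int:
        return int(self.bound.sum())

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            moment_dirs=self.moment_dirs.copy(),
            moment_mags=self.moment_mags.copy(),
            radii=self.radii.copy(),
            bound=self.bound.copy(),
            field_mT=self.field_mT.copy(),
            temperature=self.temperature,
        )

    @classmethod
    def from_particles(cls, particles, field_mT=(0.0, 0.0, 0.0),
                       temperature: float = T_REF) -> "SystemState":
        ps = list(particles)
        return cls(
            positions=np.array([p.position for p in ps], dtype=float).reshape(len(ps), 3),
            moment_dirs=np.array([p.moment_direction for p in ps], dtype=float).reshape(len(ps), 3),
            moment_mags=np.array([p.moment_magnitude for p in ps], dtype=float),
            radii=np.array([p.radius for p in ps], dtype=float),
            bound=np.array([p.bound for p in ps], dtype=bool),
            field_mT=np.asarray(field_mT, dtype=float),
            temperature=temperature,
        )
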