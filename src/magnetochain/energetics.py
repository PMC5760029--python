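"""Energy terms of the tethered dipolar-sphere model.

Four finite contributions make up the configurational energy, all
returned in units of kBT at the 300 K reference temperature:

* ``E_dd`` — the point dipole-dipole interaction between every particle
  pair, anisotropic and falling off as r^-3;
* ``E_elastic`` — the cable-linker energy 1/2 kl (l - l0)^2 for bound
  particles whose linker is stretched beyond its rest length (a cable
  carries no energy when slack);
* ``E_bind`` — a constant gain of -|Eb| per particle bound to the
  filament;
* ``E_field`` — the Zeeman energy -m.B of each moment in the external
  field.

Hard-sphere overlap is an infinite fifth term; it is handled as a
geometric constraint (:func:`hard_core_ok`) and by move rejection in the
sampler, never by infinite-energy arithmetic.

This module is the plain-numpy reference implementation.  The Monte
Carlo inner loop in :mod:`magnetochain._kernels` re-implements the same
algebra for speed; tests hold the two routes together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DIPOLE_PREF, FIELD_PREF
from .params import ModelParams
from .state import ParticleState, SystemState


class HardCoreViolationError(ValueError):
    """Raised when a configuration contains overlapping particles."""


@dataclass(frozen=True)
class EnergyDecomposition:
    """Energy terms in kBT at the 300 K reference temperature."""

    e_dd: float
    e_elastic: float
    e_bind: float
    e_field: float

    @property
    def total(self) -> float:
        return self.e_dd + self.e_elastic + self.e_bind + self.e_field

    def as_array(self) -> np.ndarray:
        return np.array([self.e_dd, self.e_elastic, self.e_bind, self.e_field])


def pair_dipole_energy(pi: ParticleState, pj: ParticleState) -> float:
    """Dipole-dipole energy of a particle pair, kBT at 300 K.

    E = -mu0/(4 pi r^3) [3 (m_i.r_hat)(m_j.r_hat) - m_i.m_j]; symmetric
    under exchange.  Coincident centres are a domain error.
    """
    rij = pj.position - pi.position
    r = float(np.linalg.norm(rij))
    if r <= 0.0:
        raise ValueError("coincident particle centres")
    # canonical sign: the energy is even in r_ij, so fixing the sign of
    # the first non-zero component makes exchange symmetry bitwise exact
    for c in rij:
        if c != 0.0:
            if c < 0.0:
                rij = -rij
            break
    r_hat = rij / r
    mi, mj = pi.moment_direction, pj.moment_direction
    # grouping keeps the expression bitwise symmetric under i <-> j
    ang = 3.0 * (float(mi @ r_hat) * float(mj @ r_hat)) - float(mi @ mj)
    return -DIPOLE_PREF * (pi.moment_magnitude * pj.moment_magnitude) * ang / r**3


def hard_core_ok(pi: ParticleState, pj: ParticleState, gap: float) -> bool:
    """True iff the pair respects the hard core, r_ij >= R_i + R_j + gap.

    Contact exactly at the boundary is allowed.
    """
    r = float(np.linalg.norm(pj.position - pi.position))
    return r >= pi.radius + pj.radius + gap


def linker_length(p: ParticleState, membrane_gap: float = 0.0) -> float:
    """Length of the shortest linker from the membrane surface of the
    particle to the filament (the x axis).

    The linker attaches to the magnetosome membrane, which envelops the
    crystal at radius R + d/2 (half the inter-particle gap d accounts
    for one membrane).  Binding can form anywhere on the membrane and
    anywhere along the filament, so the minimal-length attachment
    l = max(0, rho - R - d/2) is always the relevant one (rho = distance
    of the centre from the axis); the membrane itself cannot
    interpenetrate the filament rod, so rho >= R + d/2 for valid states
    and the clamp only handles the contact boundary.
    """
    rho = float(np.hypot(p.position[1], p.position[2]))
    return max(0.0, rho - p.radius - membrane_gap / 2.0)


def elastic_energy(l: float, params: ModelParams) -> float:
    """Cable-spring energy: 1/2 kl (l - l0)^2 beyond rest length, else 0."""
    ext = l - params.linker_rest_length
    if ext <= 0.0:
        return 0.0
    return 0.5 * params.linker_stiffness * ext * ext


def binding_energy_term(p: ParticleState, params: ModelParams) -> float:
    """Binding contribution of one particle: -|Eb| plus the elastic
    energy of its stretched linker if bound, zero if unbound."""
    if not p.bound:
        return 0.0
    l = linker_length(p, params.membrane_gap)
    return -params.binding_energy + elastic_energy(l, params)


def field_energy(p: ParticleState, field_mT) -> float:
    """Zeeman energy -m.B of one moment, kBT at 300 K (field in mT)."""
    b = np.asarray(field_mT, dtype=float)
    return -FIELD_PREF * p.moment_magnitude * float(p.moment_direction @ b)


def _pair_terms(state: SystemState) -> np.ndarray:
    """Vectorised dipole-dipole energies of all pairs (condensed order)."""
    n = state.n
    if n < 2:
        return np.zeros(0)
    iu, ju = np.triu_indices(n, k=1)
    rij = state.positions[ju] - state.positions[iu]
    r = np.linalg.norm(rij, axis=1)
    if np.any(r <= 0.0):
        raise ValueError("coincident particle centres")
    r_hat = rij / r[:, None]
    mi = state.moment_dirs[iu]
    mj = state.moment_dirs[ju]
    ang = 3.0 * np.einsum("ij,ij->i", mi, r_hat) * np.einsum("ij,ij->i", mj, r_hat) \
        - np.einsum("ij,ij->i", mi, mj)
    return -DIPOLE_PREF * state.moment_mags[iu] * state.moment_mags[ju] * ang / r**3


def check_hard_core(state: SystemState, params: ModelParams) -> None:
    """Raise :class:`HardCoreViolationError` if any pair overlaps."""
    n = state.n
    if n < 2:
        return
    iu, ju = np.triu_indices(n, k=1)
    r = np.linalg.norm(state.positions[ju] - state.positions[iu], axis=1)
    dmin = state.radii[iu] + state.radii[ju] + params.membrane_gap
    bad = r < dmin - 1e-12
    if np.any(bad):
        k = int(np.argmax(bad))
        raise HardCoreViolationError(
            f"particles {iu[k]} and {ju[k]} overlap: r = {r[k]:.6g} nm < {dmin[k]:.6g} nm"
        )


def total_energy(state: SystemState, params: ModelParams,
                 check_overlap: bool = True) -> EnergyDecomposition:
    """Full energy decomposition of a state, kBT at 300 K.

    Overlapping states are reported as a violation (they sit at +inf and
    must be rejected upstream, never summed).
    """
    if check_overlap:
        check_hard_core(state, params)
    e_dd = float(_pair_terms(state).sum())
    e_field = -FIELD_PREF * float(
        (state.moment_mags * (state.moment_dirs @ state.field_mT)).sum()
    )
    e_el = 0.0
    e_bind = 0.0
    rho = np.hypot(state.positions[:, 1], state.positions[:, 2])
    l = np.maximum(0.0, rho - state.radii - params.membrane_gap / 2.0)
    ext = np.maximum(0.0, l - params.linker_rest_length)
    for i in range(state.n):
        if state.bound[i]:
            e_bind -= params.binding_energy
            e_el += 0.5 * params.linker_stiffness * ext[i] ** 2
    return EnergyDecomposition(e_dd=e_dd, e_elastic=e_el, e_bind=e_bind, e_field=e_field)


def delta_energy(state: SystemState, proposal, params: ModelParams) -> float:
    """Energy change of a single-particle move, touching only the terms
    that involve the moved particle.

    Agrees with a full before/after recomputation to 1e-9 kBT; the
    sampler's fast path relies on the same locality.
    """
    from .mc import MoveProposal  # local import to avoid a cycle

    if not isinstance(proposal, MoveProposal):
        raise TypeError("proposal must be a MoveProposal")
    i = proposal.particle_index
    if not 0 <= i < state.n:
        raise IndexError(f"no particle {i} in a {state.n}-particle system")

    p_old = state.particle(i)
    others = [j for j in range(state.n) if j != i]

    if proposal.kind == "flip_binding":
        term_old = binding_energy_term(p_old, params)
        p_new = state.particle(i)
        p_new.bound = not p_new.bound
        return binding_energy_term(p_new, params) - term_old

    p_new = state.particle(i)
    if proposal.kind == "translate":
        p_new.position = p_old.position + np.asarray(proposal.translation, dtype=float)
    elif proposal.kind == "rotate_moment":
        from .mc import rotate_direction
        p_new.moment_direction = rotate_direction(
            p_old.moment_direction, proposal.dpolar_deg, proposal.dazimuth_deg
        )
    else:
        raise ValueError(f"unknown move kind {proposal.kind!r}")

    de = 0.0
    for j in others:
        pj = state.particle(j)
        de += pair_dipole_energy(p_new, pj) - pair_dipole_energy(p_old, pj)
    if proposal.kind == "translate":
        de += binding_energy_term(p_new, params) - binding_energy_term(p_old, params)
    else:
        de += field_energy(p_new, state.field_mT) - field_energy(p_old, state.field_mT)
    return de
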