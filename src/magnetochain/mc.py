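"""Metropolis Monte Carlo sampling and simulated annealing.

Each Monte Carlo step picks one particle uniformly at random and
attempts one of three moves, also uniformly: a translation with x, y, z
displacements drawn from [-d_n, +d_n], a rotation of its magnetic
moment by independent polar and azimuthal changes in [-5 deg, +5 deg],
or a flip of its filament-binding state.  Moves that would overlap
particles or leave the cylindrical box are rejected outright; the rest
are accepted with the Metropolis probability min(1, exp(-dE/kBT)).

Two execution paths exist.  :func:`step` is the transparent pure-Python
reference used for statistical validation.  :func:`run` and
:func:`anneal` drive the compiled kernel in :mod:`._kernels`, which is
what the experiment protocols use; its incremental energy bookkeeping is
checked against the reference recomputation in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .constants import T_REF
from .energetics import (EnergyDecomposition, delta_energy, total_energy)
from .params import ModelParams
from .state import SystemState

MOVE_KINDS = ("translate", "rotate_moment", "flip_binding")


@dataclass
class MoveProposal:
    """One attempted Monte Carlo move."""

    kind: str
    particle_index: int
    translation: Optional[np.ndarray] = None   # nm, components in [-d_n, d_n]
    dpolar_deg: float = 0.0                    # in [-5, 5]
    dazimuth_deg: float = 0.0                  # in [-5, 5]

    def __post_init__(self) -> None:
        if self.kind not in MOVE_KINDS:
            raise ValueError(f"unknown move kind {self.kind!r}")
        if self.translation is not None:
            self.translation = np.asarray(self.translation, dtype=float)


def rotate_direction(u: np.ndarray, dpolar_deg: float, dazimuth_deg: float) -> np.ndarray:
    """Perturb the lab-frame polar and azimuthal angles of a unit vector."""
    polar = math.acos(max(-1.0, min(1.0, float(u[2]))))
    azim = math.atan2(float(u[1]), float(u[0]))
    polar += math.radians(dpolar_deg)
    azim += math.radians(dazimuth_deg)
    sp = math.sin(polar)
    return np.array([sp * math.cos(azim), sp * math.sin(azim), math.cos(polar)])


def propose_move(state: SystemState, params: ModelParams,
                 rng: np.random.Generator) -> MoveProposal:
    """Draw one move proposal: uniform particle, uniform kind, uniform
    perturbation within the move ranges."""
    if state.n == 0:
        raise ValueError("cannot propose a move for an empty system")
    i = int(rng.integers(state.n))
    kind = MOVE_KINDS[int(rng.integers(3))]
    if kind == "translate":
        dn = params.contact_distance
        return MoveProposal(kind, i, translation=rng.uniform(-dn, dn, size=3))
    if kind == "rotate_moment":
        a = params.max_rotation_deg
        return MoveProposal(kind, i,
                            dpolar_deg=float(rng.uniform(-a, a)),
                            dazimuth_deg=float(rng.uniform(-a, a)))
    return MoveProposal(kind, i)


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dE/kBT)).

    ``delta_e`` is in kBT at 300 K; ``temperature`` in K rescales it.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-delta_e * T_REF / temperature)


def _move_valid(state: SystemState, proposal: MoveProposal,
                params: ModelParams) -> bool:
    """Geometric validity of a translation: inside the box, no overlap."""
    if proposal.kind != "translate":
        return True
    i = proposal.particle_index
    new = state.positions[i] + proposal.translation
    if abs(new[0]) > params.cylinder_length / 2.0:
        return False
    rho2 = new[1] ** 2 + new[2] ** 2
    if rho2 > params.cylinder_radius ** 2:
        return False
    # the filament is a rigid rod: the membrane (R + d/2) cannot
    # interpenetrate it
    if rho2 < (state.radii[i] + params.membrane_gap / 2.0) ** 2:
        return False
    for j in range(state.n):
        if j == i:
            continue
        dmin = params.pair_contact_distance(state.radii[i], state.radii[j])
        if np.sum((state.positions[j] - new) ** 2) < dmin * dmin:
            return False
    return True


def apply_move(state: SystemState, proposal: MoveProposal) -> None:
    """Apply an (already accepted) proposal in place."""
    i = proposal.particle_index
    if proposal.kind == "translate":
        state.positions[i] += proposal.translation
    elif proposal.kind == "rotate_moment":
        state.moment_dirs[i] = rotate_direction(
            state.moment_dirs[i], proposal.dpolar_deg, proposal.dazimuth_deg)
    else:
        state.bound[i] = not state.bound[i]


def step(state: SystemState, params: ModelParams,
         rng: np.random.Generator) -> bool:
    """One reference Metropolis step, in place.  Returns True if the
    proposal was accepted (hard-core and box violations are rejected
    unconditionally)."""
    proposal = propose_move(state, params, rng)
    if not _move_valid(state, proposal, params):
        return False
    de = delta_energy(state, proposal, params)
    if metropolis_accept(de, state.temperature, rng):
        apply_move(state, proposal)
        return True
    return False


@dataclass
class AnnealingSchedule:
    """Geometric cooling ladder from ``t_start`` down to ``t_final``.

    The default starts at 3e4 K, where kBT equals one magnetic contact
    bond (~100 kBT at 300 K) so any bond breaks freely, and cools
    geometrically over 60 stages of 1e5 attempts each down to 300 K.
    This places roughly a third of the stages in the coalescence window
    (bond strengths of 1-10 kBT) where cluster growth and ring opening
    actually happen.
    """

    t_start: float = 3.0e4
    t_final: float = 300.0
    n_stages: int = 60
    steps_per_stage: int = 100_000

    def __post_init__(self) -> None:
        if not self.t_start >= self.t_final > 0:
            raise ValueError("need t_start >= t_final > 0")
        if self.n_stages < 1 or self.steps_per_stage < 0:
            raise ValueError("n_stages >= 1 and steps_per_stage >= 0 required")

    @property
    def cooling_factor(self) -> float:
        """Per-stage geometric factor alpha implied by the endpoints."""
        if self.n_stages == 1 or self.t_start == self.t_final:
            return 1.0
        return (self.t_final / self.t_start) ** (1.0 / (self.n_stages - 1))

    def stage_temperatures(self) -> np.ndarray:
        """Monotone non-increasing geometric ladder, K."""
        if self.n_stages == 1:
            return np.array([self.t_final])
        return self.t_start * self.cooling_factor ** np.arange(self.n_stages)

    @property
    def total_steps(self) -> int:
        return self.n_stages * self.steps_per_stage

    def scaled(self, factor: float) -> "AnnealingSchedule":
        """Same ladder with steps_per_stage scaled by ``factor``."""
        return AnnealingSchedule(self.t_start, self.t_final, self.n_stages,
                                 max(1, int(round(self.steps_per_stage * factor))))


class Engine:
    """Drives the compiled kernel over a :class:`SystemState` in place,
    maintaining an incrementally updated energy decomposition.

    One engine owns one run's RNG stream: construct with a seed, then
    any sequence of :meth:`run` calls is bit-reproducible.  Pass
    ``mobile`` to freeze a subset of particles (used e.g. by the
    two-particle oracle cross-check).
    """

    def __init__(self, state: SystemState, params: ModelParams,
                 seed: Optional[int] = None,
                 mobile: Optional[Sequence[int]] = None) -> None:
        self.state = state
        self.params = params
        if mobile is None:
            mobile = np.arange(state.n)
        self.mobile = np.ascontiguousarray(mobile, dtype=np.int64)
        if seed is not None:
            _kernels.seed_rng(int(seed))
        dec = total_energy(state, params)
        self._e_acc = np.array([dec.e_dd, dec.e_elastic, dec.e_bind, dec.e_field])
        self.accepted = 0
        self.attempts = 0

    @property
    def energies(self) -> EnergyDecomposition:
        """Current (incrementally maintained) decomposition, kBT at 300 K."""
        return EnergyDecomposition(*self._e_acc)

    def resync_energies(self) -> None:
        """Replace the running decomposition by a from-scratch one."""
        dec = total_energy(self.state, self.params)
        self._e_acc[:] = dec.as_array()

    def run(self, n_steps: int, temperature: Optional[float] = None,
            sample_every: int = 0) -> np.ndarray:
        """Run ``n_steps`` move attempts at the given temperature
        (default: the state's).  Returns [n_samples, mean_bound,
        mean_theta_m] accumulated every ``sample_every`` attempts
        (zeros if sampling is off)."""
        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        st, p = self.state, self.params
        if temperature is None:
            temperature = st.temperature
        stats = np.zeros(3)
        if n_steps == 0:
            return stats
        acc = _kernels.run_kernel(
            st.positions, st.moment_dirs, st.moment_mags, st.radii, st.bound,
            int(n_steps), T_REF / temperature,
            float(st.field_mT[0]), float(st.field_mT[1]), float(st.field_mT[2]),
            p.membrane_gap, p.contact_distance, math.radians(p.max_rotation_deg),
            p.linker_stiffness, p.linker_rest_length, p.binding_energy,
            p.cylinder_radius ** 2, p.cylinder_length / 2.0,
            self.mobile, self._e_acc, int(sample_every), stats)
        self.accepted += int(acc)
        self.attempts += int(n_steps)
        st.temperature = temperature
        if stats[0] > 0:
            stats[1] /= stats[0]
            stats[2] /= stats[0]
        return stats

    def set_field(self, field_mT) -> None:
        self.state.field_mT = np.asarray(field_mT, dtype=float)
        # the Zeeman term depends on the field; refresh it exactly
        self.resync_energies()


def run(state: SystemState, params: ModelParams, n_steps: int,
        seed: Optional[int] = None,
        recorders: Sequence[Callable] = (),
        record_interval: int = 10_000,
        temperature: Optional[float] = None) -> SystemState:
    """Fixed-temperature run of ``n_steps`` attempts, in place.

    ``recorders`` are callables ``(attempt_index, state, energies)``
    invoked every ``record_interval`` attempts (and once at the end).
    Bit-reproducible for a fixed seed.
    """
    eng = Engine(state, params, seed=seed)
    done = 0
    for rec in recorders:
        rec(0, state, eng.energies)
    while done < n_steps:
        chunk = min(record_interval, n_steps - done)
        eng.run(chunk, temperature=temperature)
        done += chunk
        for rec in recorders:
            rec(done, state, eng.energies)
    return state


def anneal(state: SystemState, params: ModelParams,
           schedule: AnnealingSchedule, seed: Optional[int] = None) -> SystemState:
    """Simulated annealing: run steps_per_stage attempts at each stage
    temperature of the schedule, from hot to cold, in place."""
    eng = Engine(state, params, seed=seed)
    for t in schedule.stage_temperatures():
        eng.run(schedule.steps_per_stage, temperature=float(t))
    state.temperature = float(schedule.stage_temperatures()[-1])
    return state
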