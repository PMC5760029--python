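"""Scripted experiments: structure census, binding/field phase grid,
field-rotation rupture sweeps, post-rupture recovery, and bulk-like
ensemble averaging.

Each protocol builds its own initial states, drives the Monte Carlo
engine and reduces the trajectories to tabular results (pandas
DataFrames) plus detected events.  All randomness derives from one
integer seed per protocol invocation; replicas use consecutive derived
seeds, so every result is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import T_REF
from .mc import AnnealingSchedule, Engine
from .observables import (CriticalAngles, chain_moment_angle,
                          classify_structures, detect_critical_angles,
                          neighbor_graph)
from .params import ModelParams
from .state import SystemState

#: Desk-scale default: MC attempts per 1-degree field increment (the
#: quasi-static reference rate is 1e7).  Rupture events are thermally
#: activated, so faster rotation finds them at somewhat larger angles;
#: 1e6 keeps a 30-sweep campaign within minutes while staying close to
#: the quasi-static events.  Raise via ``steps_scale`` for slower,
#: more quasi-static rotation.
DEFAULT_STEPS_PER_INCREMENT = 1_000_000


@dataclass
class RotationProtocol:
    """Quasi-static rotation of the field away from the filament axis.

    The field of magnitude ``field_mT`` starts at ``theta_start`` from
    the +x axis and advances by ``theta_step`` every
    ``steps_per_increment`` attempts, staying in the x-y plane (the
    rotation axis z is perpendicular to the chain/field plane).
    """

    field_mT: float = 50.0
    theta_start: float = 0.0
    theta_end: float = 90.0
    theta_step: float = 1.0
    steps_per_increment: int = DEFAULT_STEPS_PER_INCREMENT
    samples_per_increment: int = 400

    def __post_init__(self) -> None:
        if self.theta_step <= 0:
            raise ValueError("theta_step must be > 0")
        if self.steps_per_increment < 1:
            raise ValueError("steps_per_increment must be >= 1")

    def angles(self) -> np.ndarray:
        n = int(round((self.theta_end - self.theta_start) / self.theta_step))
        return self.theta_start + self.theta_step * np.arange(1, n + 1)


@dataclass
class RecoveryProtocol:
    """Post-rupture scenario: field switched off, or realigned with the
    filament at full strength."""

    mode: str = "field_off"            # or "field_aligned"
    duration: int = 50_000_000          # MC attempts
    check_interval: int = 20_000        # attempts between criterion checks
    theta_band_deg: float = 10.0        # theta_m recovery band around the axis
    bound_fraction: float = 0.9         # of the pre-rupture bound count

    def __post_init__(self) -> None:
        if self.mode not in ("field_off", "field_aligned"):
            raise ValueError(f"unknown recovery mode {self.mode!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class BulkEnsembleSpec:
    """Cell-to-cell variability for bulk-sample-like averaging.

    ``polydisperse`` draws each replica's particle radii from a
    truncated Gaussian (electron-microscopy size distribution: mean
    20.3 nm, sd 6.8 nm) with moments scaling as R^3; ``orientation``
    varies the initial chain-field misalignment over a grid and weights
    replicas by a Fisher density of concentration kappa.
    """

    mode: str = "polydisperse"          # or "orientation"
    n_replicas: int = 10
    mean_radius: float = 20.3           # nm
    sd_radius: float = 6.8              # nm
    radius_bounds: tuple = (5.0, 40.0)  # nm, truncation by resampling
    kappa: float = 10.0                 # Fisher concentration
    max_misalignment_deg: float = 30.0  # orientation-grid half-width

    def __post_init__(self) -> None:
        if self.mode not in ("polydisperse", "orientation"):
            raise ValueError(f"unknown bulk mode {self.mode!r}")
        if self.n_replicas < 2:
            raise ValueError("n_replicas must be >= 2")
        lo, hi = self.radius_bounds
        if not 0 < lo < hi:
            raise ValueError("radius bounds must satisfy 0 < lo < hi")


def draw_radii(spec: BulkEnsembleSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-Gaussian particle radii (resampling until in bounds)."""
    lo, hi = spec.radius_bounds
    out = np.empty(n)
    for i in range(n):
        while True:
            r = rng.normal(spec.mean_radius, spec.sd_radius)
            if lo <= r <= hi:
                out[i] = r
                break
    return out


def make_initial_state(params: ModelParams, mode: str = "random",
                       seed: int = 0, radii: Optional[np.ndarray] = None,
                       max_tries: int = 100_000) -> SystemState:
    """Build a starting configuration.

    ``random``: rejection-sample non-overlapping centres uniformly in
    the cylinder, uniform random moment directions, all unbound.
    ``chain_on_filament``: particles at contact spacing along the
    filament, centred on the origin, moments along +x, all bound.
    """
    n = params.n_particles
    if radii is None:
        radii = np.full(n, params.particle_radius)
    else:
        radii = np.asarray(radii, dtype=float)
        if len(radii) != n:
            raise ValueError("radii length must equal n_particles")
    mags = np.array([
        params.msat * (4.0 / 3.0) * math.pi * (r * 1e-9) ** 3 for r in radii
    ]) if np.any(radii != params.particle_radius) else np.full(n, params.dipole_moment)

    if mode == "chain_on_filament":
        # chain lies alongside the filament rod with the membrane
        # touching it (centres at rho = R_i + d/2, slack linkers), on
        # the +y side toward which the standard rotation protocol tilts
        # the field
        y = radii + params.membrane_gap / 2.0
        x = np.zeros(n)
        for i in range(1, n):
            dn = params.pair_contact_distance(radii[i - 1], radii[i])
            dy = y[i] - y[i - 1]
            x[i] = x[i - 1] + math.sqrt(max(dn * dn - dy * dy, 0.0))
        x -= x.mean()
        positions = np.column_stack([x, y, np.zeros(n)])
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        bound = np.ones(n, dtype=bool)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        positions = np.empty((n, 3))
        half = params.cylinder_length / 2.0
        placed = 0
        tries = 0
        while placed < n:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"failed to pack {n} particles after {max_tries} tries")
            x = rng.uniform(-half, half)
            rho = params.cylinder_radius * math.sqrt(rng.uniform())
            if rho < radii[placed] + params.membrane_gap / 2.0:
                continue                  # membrane would enclose the rod
            phi = rng.uniform(0.0, 2.0 * math.pi)
            cand = np.array([x, rho * math.cos(phi), rho * math.sin(phi)])
            ok = True
            for j in range(placed):
                dmin = params.pair_contact_distance(radii[placed], radii[j])
                if np.sum((positions[j] - cand) ** 2) < dmin * dmin:
                    ok = False
                    break
            if ok:
                positions[placed] = cand
                placed += 1
        v = rng.normal(size=(n, 3))
        dirs = v / np.linalg.norm(v, axis=1)[:, None]
        bound = np.zeros(n, dtype=bool)
    else:
        raise ValueError(f"unknown initial-state mode {mode!r}")

    return SystemState(
        positions=positions, moment_dirs=dirs, moment_mags=mags,
        radii=radii, bound=bound,
        field_mT=np.array(params.field_vector()), temperature=params.temperature,
    )


def equilibrium_bound_probability(params: ModelParams,
                                  temperature: float = T_REF) -> float:
    """Equilibrium probability that an on-axis particle is bound.

    Binding with a slack linker trades the state entropy against the
    gain |Eb|: p = 1 / (1 + exp(-|Eb|/kBT)).  Used to scale rupture-
    detection thresholds: when k particles detach for good, the
    time-averaged bound count drops by k*p, not k.
    """
    x = params.binding_energy * T_REF / temperature
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# structure census and phase grid
# ---------------------------------------------------------------------------

def equilibrium_census(params: ModelParams, n_runs: int = 100,
                       schedule: Optional[AnnealingSchedule] = None,
                       seed: int = 0,
                       eb_values: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Anneal ``n_runs`` random initial states per binding energy and
    classify the final structures.

    Returns one row per (|Eb|, run) with the configuration label (the
    type of the unique non-singleton cluster, or 'other'), the cluster
    counts and the bound count.  Fractions per class are obtained by
    grouping on ``eb`` and ``label``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if schedule is None:
        schedule = AnnealingSchedule()
    if eb_values is None:
        eb_values = [params.binding_energy]
    rows = []
    run_id = 0
    for eb in eb_values:
        p = params.replace(binding_energy=float(eb))
        for k in range(n_runs):
            st = make_initial_state(p, "random", seed=seed + 7919 * run_id)
            eng = Engine(st, p, seed=seed + 7919 * run_id + 1)
            for t in schedule.stage_temperatures():
                eng.run(schedule.steps_per_stage, temperature=float(t))
            rep = classify_structures(neighbor_graph(st, p), st)
            rows.append({
                "eb": float(eb), "run": k, "label": rep.config_label(),
                "n_chains": rep.n_chains, "n_rings": rep.n_rings,
                "n_handles": rep.n_handles, "n_other": rep.n_other,
                "bound_count": rep.bound_count,
            })
            run_id += 1
    return pd.DataFrame(rows)


def census_fractions(census: pd.DataFrame) -> pd.DataFrame:
    """Fraction of configurations per class, per binding energy."""
    frac = (census.groupby("eb")["label"]
            .value_counts(normalize=True).unstack(fill_value=0.0))
    for lab in ("chain", "ring", "handle", "other"):
        if lab not in frac.columns:
            frac[lab] = 0.0
    return frac[["chain", "ring", "handle", "other"]]


def phase_grid(eb_values: Sequence[float], b_values: Sequence[float],
               params: ModelParams, n_seeds: int = 5,
               schedule: Optional[AnnealingSchedule] = None,
               seed: int = 0, field_angle_deg: float = 90.0) -> pd.DataFrame:
    """Mean number of chains and bound particles over the binding-energy
    x field-strength grid, field fixed at ``field_angle_deg`` to the
    filament; means over ``n_seeds`` annealed runs, rounded to integers.
    """
    if len(eb_values) == 0 or len(b_values) == 0:
        raise ValueError("grids must be non-empty")
    if schedule is None:
        schedule = AnnealingSchedule()
    rows = []
    cell = 0
    for eb in eb_values:
        for b in b_values:
            p = params.replace(binding_energy=float(eb), field_mT=float(b),
                               field_angle_deg=field_angle_deg)
            chains = []
            bound = []
            for k in range(n_seeds):
                s = seed + 104729 * cell + 2 * k
                st = make_initial_state(p, "random", seed=s)
                eng = Engine(st, p, seed=s + 1)
                for t in schedule.stage_temperatures():
                    eng.run(schedule.steps_per_stage, temperature=float(t))
                rep = classify_structures(neighbor_graph(st, p), st)
                n_cl = sum(1 for lab, mem in rep.clusters if len(mem) >= 2)
                chains.append(n_cl)
                bound.append(rep.bound_count)
            rows.append({
                "eb": float(eb), "field_mT": float(b),
                "mean_n_chains": int(round(float(np.mean(chains)))),
                "mean_bound": int(round(float(np.mean(bound)))),
            })
            cell += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rupture sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-angle trace and detected rupture events of one sweep."""

    seed: int
    trace: pd.DataFrame
    critical: CriticalAngles
    final_state: SystemState


def _sweep_one(state: SystemState, params: ModelParams,
               protocol: RotationProtocol, seed: Optional[int],
               mobile: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Rotate the field over a pre-built state; per-increment rows."""
    eng = Engine(state, params, seed=seed, mobile=mobile)
    b = protocol.field_mT
    sample_every = max(1, protocol.steps_per_increment
                       // max(1, protocol.samples_per_increment))
    rows = []
    for th in protocol.angles():
        rad = math.radians(th)
        eng.set_field([b * math.cos(rad), b * math.sin(rad), 0.0])
        stats = eng.run(protocol.steps_per_increment, sample_every=sample_every)
        rep = classify_structures(neighbor_graph(state, params), state)
        e = eng.energies
        snap_theta = chain_moment_angle(state)
        rows.append({
            "theta_b": float(th),
            "bound_mean": float(stats[1]),
            "bound_snap": state.bound_count(),
            "theta_m_mean": float(stats[2]),
            "theta_m_snap": math.nan if snap_theta is None else snap_theta,
            "e_dd": e.e_dd, "e_elastic": e.e_elastic,
            "e_bind": e.e_bind, "e_field": e.e_field,
            "n_chains": rep.n_chains, "n_rings": rep.n_rings,
            "n_handles": rep.n_handles, "n_other": rep.n_other,
        })
    return pd.DataFrame(rows)


def detect_sweep_events(trace: pd.DataFrame, params: ModelParams,
                        window_deg: float = 4.0) -> CriticalAngles:
    """Change-point detection on the time-averaged sweep trace.

    The nominal thresholds (detachment of a chain end, a bound-count
    drop of N/4 or a 15-degree theta_m jump for fragmentation) are
    scaled by the equilibrium bound probability p_eq, because a
    permanently detached particle removes only p_eq from the
    *time-averaged* bound count.  The first event fires on a single
    detached end (threshold 0.75 p_eq): with the chain lying on one
    side of the filament rod, the in-plane escape path is open to one
    end at a time, so end detachment proceeds end by end rather than
    pairwise.  The default window is 4 degrees: at the desk-scale
    rotation rate a detaching end rebinds intermittently, ramping the
    averaged signal over a few degrees rather than stepping sharply.
    """
    p_eq = equilibrium_bound_probability(params)
    return detect_critical_angles(
        trace["theta_b"], trace["bound_mean"], trace["theta_m_mean"],
        n_particles=params.n_particles, window_deg=window_deg,
        first_drop=0.75 * p_eq,
        second_drop=params.n_particles / 4.0 * p_eq,
        theta_m_jump=15.0,
    )


def rupture_sweep(params: ModelParams, protocol: RotationProtocol,
                  seeds: Sequence[int] = tuple(range(10))) -> list[SweepResult]:
    """Rotate the field over a pre-assembled bound chain, one sweep per
    seed (10 by default), detecting the two critical angles from the
    bound-count / theta_m traces."""
    results = []
    for s in seeds:
        params_run = params.replace(field_mT=protocol.field_mT,
                                    field_angle_deg=protocol.theta_start)
        st = make_initial_state(params_run, "chain_on_filament")
        trace = _sweep_one(st, params_run, protocol, seed=int(s))
        crit = detect_sweep_events(trace, params_run)
        results.append(SweepResult(seed=int(s), trace=trace,
                                   critical=crit, final_state=st))
    return results


def two_particle_unbinding_angle(params: ModelParams, field_mT: float = 50.0,
                                 seed: int = 0,
                                 steps_per_increment: int = 200_000,
                                 theta_max: float = 80.0) -> Optional[float]:
    """Field angle at which a single tethered particle detaches from the
    filament, measured by Monte Carlo.

    Mirrors the closed-form two-particle criterion: one dipole is a
    boundary condition (position fixed at the chain site, moment locked
    to the field direction, per the aligned-moments assumption of the
    closed form), the other is a bound, mobile particle.  The field is
    rotated quasi-statically; returns the first angle at which the
    mobile particle's time-averaged bound fraction falls below 1/2, or
    None if it stays attached up to ``theta_max``.
    """
    p = params.replace(n_particles=2, field_mT=field_mT, field_angle_deg=0.0)
    y0 = p.particle_radius + p.membrane_gap / 2.0
    st = SystemState(
        positions=np.array([[0.0, y0, 0.0], [p.contact_distance, y0, 0.0]]),
        moment_dirs=np.tile([1.0, 0.0, 0.0], (2, 1)),
        moment_mags=np.full(2, p.dipole_moment),
        radii=np.full(2, p.particle_radius),
        bound=np.array([True, True]),
        field_mT=np.array([field_mT, 0.0, 0.0]))
    eng = Engine(st, p, seed=seed, mobile=np.array([1]))
    sample_every = max(1, steps_per_increment // 400)
    for th in np.arange(1.0, theta_max + 1.0):
        rad = math.radians(th)
        st.moment_dirs[0] = [math.cos(rad), math.sin(rad), 0.0]
        eng.set_field([field_mT * math.cos(rad), field_mT * math.sin(rad), 0.0])
        stats = eng.run(steps_per_increment, sample_every=sample_every)
        if stats[1] - 1.0 < 0.5:        # the fixed particle stays bound
            return float(th)
    return None


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """First-passage times (MC attempts) to the recovery criteria.

    ``None`` marks a criterion not met within the protocol duration
    (censored).
    """

    theta_time: Optional[int]
    bound_time: Optional[int]
    duration: int
    baseline_bound: float

    @property
    def theta_censored(self) -> bool:
        return self.theta_time is None

    @property
    def bound_censored(self) -> bool:
        return self.bound_time is None


def recovery_run(state: SystemState, protocol: RecoveryProtocol,
                 params: ModelParams, seed: int = 0,
                 baseline_bound: Optional[float] = None) -> RecoveryResult:
    """Simulate chain re-formation after rupture.

    The input is a post-rupture state (e.g. the final state of a sweep
    at 90 degrees).  In ``field_off`` mode the field is removed; in
    ``field_aligned`` mode it keeps its magnitude but points along the
    filament.  Reports the first times the interval-averaged theta_m
    enters the recovery band and the bound count reaches the criterion
    fraction of the pre-rupture (equilibrium) bound count.
    """
    if baseline_bound is None:
        baseline_bound = params.n_particles * equilibrium_bound_probability(params)
    st = state.copy()
    b = float(np.linalg.norm(st.field_mT))
    if protocol.mode == "field_off":
        st.field_mT = np.zeros(3)
    else:
        st.field_mT = np.array([b, 0.0, 0.0])
    eng = Engine(st, params, seed=seed)
    sample_every = max(1, protocol.check_interval // 20)
    theta_time = None
    bound_time = None
    done = 0
    # time 0 check on the instantaneous state (an intact input recovers
    # immediately)
    th0 = chain_moment_angle(st)
    if th0 is not None and th0 <= protocol.theta_band_deg:
        theta_time = 0
    if st.bound_count() >= protocol.bound_fraction * baseline_bound:
        bound_time = 0
    while done < protocol.duration and (theta_time is None or bound_time is None):
        chunk = min(protocol.check_interval, protocol.duration - done)
        stats = eng.run(chunk, sample_every=sample_every)
        done += chunk
        if theta_time is None and stats[2] <= protocol.theta_band_deg:
            theta_time = done
        if bound_time is None and stats[1] >= protocol.bound_fraction * baseline_bound:
            bound_time = done
    return RecoveryResult(theta_time=theta_time, bound_time=bound_time,
                          duration=protocol.duration,
                          baseline_bound=float(baseline_bound))


# ---------------------------------------------------------------------------
# bulk-like ensemble averaging
# ---------------------------------------------------------------------------

def bulk_average(spec: BulkEnsembleSpec, protocol: RotationProtocol,
                 params: ModelParams, seed: int = 0) -> pd.DataFrame:
    """Bulk-sample-like rupture curve: replica sweeps averaged over
    cell-to-cell variability.

    Polydisperse mode: each replica draws its own particle radii (and
    R^3-scaled moments) and runs the rotation sweep; the mean trace is
    unweighted.  Orientation mode: replicas start with the chain
    misaligned from the initial field by angles on a uniform grid, and
    the mean is weighted by the Fisher (von Mises-Fisher) density
    exp(kappa * cos(psi)) of the misalignment psi.

    Returns a DataFrame with theta_b, the averaged theta_m and bound
    count, and one theta_m column per replica.
    """
    rng = np.random.default_rng(seed)
    traces = []
    weights = []
    for rep in range(spec.n_replicas):
        rep_seed = seed + 15485863 * (rep + 1)
        if spec.mode == "polydisperse":
            radii = draw_radii(spec, params.n_particles, rng)
            params_run = params.replace(field_mT=protocol.field_mT,
                                        field_angle_deg=protocol.theta_start)
            st = make_initial_state(params_run, "chain_on_filament", radii=radii)
            trace = _sweep_one(st, params_run, protocol, seed=rep_seed)
            weights.append(1.0)
        else:
            if spec.n_replicas == 1:
                psi = 0.0
            else:
                psi = (-spec.max_misalignment_deg
                       + 2.0 * spec.max_misalignment_deg * rep / (spec.n_replicas - 1))
            # misaligning the chain by psi relative to the initial field
            # is equivalent to starting the field sweep offset by -psi
            shifted = RotationProtocol(
                field_mT=protocol.field_mT,
                theta_start=protocol.theta_start - psi,
                theta_end=protocol.theta_end - psi,
                theta_step=protocol.theta_step,
                steps_per_increment=protocol.steps_per_increment,
                samples_per_increment=protocol.samples_per_increment)
            params_run = params.replace(field_mT=protocol.field_mT)
            st = make_initial_state(params_run, "chain_on_filament")
            trace = _sweep_one(st, params_run, shifted, seed=rep_seed)
            trace = trace.assign(theta_b=trace["theta_b"] + psi)
            weights.append(math.exp(spec.kappa
                                    * (math.cos(math.radians(psi)) - 1.0)))
        traces.append(trace)
    w = np.asarray(weights)
    w = w / w.sum()
    out = pd.DataFrame({"theta_b": traces[0]["theta_b"]})
    tm = np.stack([t["theta_m_mean"].to_numpy() for t in traces])
    bc = np.stack([t["bound_mean"].to_numpy() for t in traces])
    out["theta_m_mean"] = w @ tm
    out["bound_mean"] = w @ bc
    for k, t in enumerate(traces):
        out[f"theta_m_rep{k}"] = t["theta_m_mean"].to_numpy()
    return out
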