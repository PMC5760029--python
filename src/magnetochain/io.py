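"""Configuration, trajectory and metadata I/O.

Run configurations are YAML with two blocks, ``model`` (physical
parameters) and ``protocol`` (exactly one experiment and its settings),
plus top-level ``seed``, ``output_dir``, ``record_interval`` and
``steps_scale``.  Unknown keys anywhere are an error, so typos never
pass silently.

Trajectories use an extended-XYZ dialect: per frame, an atom count
line, a comment line of ``key=value`` pairs (step, temperature, field
angle, energy decomposition and a ``Properties`` descriptor), then one
line per particle with species tag, position (nm), moment unit vector,
radius (nm) and bound flag.  Files are valid XYZ supersets and load in
standard molecular viewers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .energetics import EnergyDecomposition
from .mc import AnnealingSchedule
from .params import ModelParams
from .protocols import (BulkEnsembleSpec, RecoveryProtocol, RotationProtocol)
from .state import SystemState

PROTOCOL_KINDS = ("census", "grid", "rupture", "recover", "bulk", "analytic")


@dataclass
class RunConfig:
    """Validated configuration of one run."""

    model: ModelParams
    protocol_kind: str
    protocol_options: dict
    seed: int = 0
    output_dir: str = "runs"
    record_interval: int = 10_000
    steps_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.protocol_kind not in PROTOCOL_KINDS:
            raise ValueError(
                f"unknown protocol {self.protocol_kind!r}; expected one of "
                f"{PROTOCOL_KINDS}")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        if self.steps_scale <= 0:
            raise ValueError("steps_scale must be > 0")

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "protocol": {"kind": self.protocol_kind, **self.protocol_options},
            "seed": int(self.seed),
            "output_dir": self.output_dir,
            "record_interval": int(self.record_interval),
            "steps_scale": float(self.steps_scale),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def config_from_dict(d: dict) -> RunConfig:
    """Build a validated RunConfig from nested plain dicts."""
    if not isinstance(d, dict):
        raise ValueError("configuration must be a mapping")
    known_top = {"model", "protocol", "seed", "output_dir",
                 "record_interval", "steps_scale"}
    unknown = set(d) - known_top
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    model = ModelParams.from_dict(dict(d.get("model", {})))
    proto = dict(d.get("protocol", {}))
    if "kind" not in proto:
        raise ValueError("protocol block must contain a 'kind'")
    kind = proto.pop("kind")
    cfg = RunConfig(
        model=model,
        protocol_kind=kind,
        protocol_options=proto,
        seed=d.get("seed", 0),
        output_dir=d.get("output_dir", "runs"),
        record_interval=d.get("record_interval", 10_000),
        steps_scale=d.get("steps_scale", 1.0),
    )
    # validate protocol options eagerly so bad configs fail on read
    build_protocol(cfg)
    return cfg


def _take(opts: dict, cls, **extra):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(opts) - names
    if unknown:
        raise ValueError(
            f"unknown option(s) for {cls.__name__}: {sorted(unknown)}")
    return cls(**opts, **extra)


def build_protocol(cfg: RunConfig):
    """Instantiate the protocol descriptor named by the config.

    Returns the descriptor object (RotationProtocol, RecoveryProtocol,
    BulkEnsembleSpec, AnnealingSchedule-based dict for census/grid, or
    None for analytic).  ``steps_scale`` multiplies all step counts.
    """
    opts = dict(cfg.protocol_options)
    scale = cfg.steps_scale
    kind = cfg.protocol_kind
    if kind in ("census", "grid"):
        sched_opts = dict(opts.pop("schedule", {}))
        schedule = _take(sched_opts, AnnealingSchedule).scaled(scale)
        known = {"census": {"n_runs", "eb_values"},
                 "grid": {"n_seeds", "eb_values", "b_values", "field_angle_deg"}}[kind]
        unknown = set(opts) - known
        if unknown:
            raise ValueError(f"unknown option(s) for {kind}: {sorted(unknown)}")
        return {"schedule": schedule, **opts}
    if kind == "rupture":
        proto = _take(opts, RotationProtocol)
        return dataclasses.replace(
            proto, steps_per_increment=max(1, int(proto.steps_per_increment * scale)))
    if kind == "recover":
        proto = _take(opts, RecoveryProtocol)
        return dataclasses.replace(
            proto, duration=max(1, int(proto.duration * scale)))
    if kind == "bulk":
        rot_opts = dict(opts.pop("rotation", {}))
        rotation = _take(rot_opts, RotationProtocol)
        rotation = dataclasses.replace(
            rotation,
            steps_per_increment=max(1, int(rotation.steps_per_increment * scale)))
        spec = _take(opts, BulkEnsembleSpec)
        return {"spec": spec, "rotation": rotation}
    return None  # analytic needs no descriptor


def read_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ValueError(f"empty configuration file: {path}")
    return config_from_dict(data)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trajectory frames (extended XYZ)
# ---------------------------------------------------------------------------

_PROPERTIES = "species:S:1:pos:R:3:moment:R:3:radius:R:1:bound:I:1:mmag:R:1"


@dataclass
class TrajectoryFrame:
    """One snapshot: metadata scalars plus the particle table."""

    step: int
    temperature: float
    theta_b_deg: float
    energies: EnergyDecomposition
    positions: np.ndarray
    moment_dirs: np.ndarray
    moment_mags: np.ndarray
    radii: np.ndarray
    bound: np.ndarray

    @classmethod
    def from_state(cls, state: SystemState, step: int,
                   energies: EnergyDecomposition) -> "TrajectoryFrame":
        b = state.field_mT
        theta = math.degrees(math.atan2(float(np.hypot(b[1], b[2])), float(b[0]))) \
            if np.linalg.norm(b) > 0 else 0.0
        return cls(step=step, temperature=state.temperature, theta_b_deg=theta,
                   energies=energies,
                   positions=state.positions.copy(),
                   moment_dirs=state.moment_dirs.copy(),
                   moment_mags=state.moment_mags.copy(),
                   radii=state.radii.copy(), bound=state.bound.copy())

    def to_state(self, field_mT=None) -> SystemState:
        return SystemState(
            positions=self.positions.copy(), moment_dirs=self.moment_dirs.copy(),
            moment_mags=self.moment_mags.copy(), radii=self.radii.copy(),
            bound=self.bound.copy(),
            field_mT=np.zeros(3) if field_mT is None else np.asarray(field_mT, float),
            temperature=self.temperature)


def write_trajectory(frames, path) -> None:
    """Write frames as extended XYZ; an empty list yields an empty file."""
    frames = list(frames)
    if frames:
        n0 = len(frames[0].positions)
        for f in frames:
            if len(f.positions) != n0:
                raise ValueError("all frames of a file must share one particle count")
    with open(path, "w") as fh:
        for f in frames:
            e = f.energies
            fh.write(f"{len(f.positions)}\n")
            fh.write(
                f'step={f.step} temperature={f.temperature:.17g} '
                f'theta_b={f.theta_b_deg:.17g} e_dd={e.e_dd:.17g} '
                f'e_elastic={e.e_elastic:.17g} e_bind={e.e_bind:.17g} '
                f'e_field={e.e_field:.17g} '
                f'Properties={_PROPERTIES}\n')
            for i in range(len(f.positions)):
                x, y, z = f.positions[i]
                mx, my, mz = f.moment_dirs[i]
                fh.write(
                    f"M {x:.17g} {y:.17g} {z:.17g} "
                    f"{mx:.17g} {my:.17g} {mz:.17g} "
                    f"{f.radii[i]:.17g} {int(f.bound[i])} "
                    f"{f.moment_mags[i]:.17g}\n")


def _parse_comment(line: str) -> dict:
    out = {}
    for tok in line.split():
        if "=" not in tok:
            raise ValueError(f"malformed key=value token {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def read_trajectory(path) -> list:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as err:
            raise ValueError(f"line {k + 1}: expected an atom count") from err
        if k + 1 + n >= len(lines) + 1 and n > 0:
            raise ValueError(f"line {k + 1}: truncated frame")
        meta = _parse_comment(lines[k + 1])
        pos = np.zeros((n, 3))
        dirs = np.zeros((n, 3))
        radii = np.zeros(n)
        bound = np.zeros(n, dtype=bool)
        mmag = np.zeros(n)
        for i in range(n):
            parts = lines[k + 2 + i].split()
            if len(parts) != 10:
                raise ValueError(
                    f"line {k + 3 + i}: expected 10 columns, got {len(parts)}")
            pos[i] = [float(v) for v in parts[1:4]]
            dirs[i] = [float(v) for v in parts[4:7]]
            radii[i] = float(parts[7])
            bound[i] = bool(int(parts[8]))
            mmag[i] = float(parts[9])
        frames.append(TrajectoryFrame(
            step=int(meta["step"]),
            temperature=float(meta["temperature"]),
            theta_b_deg=float(meta["theta_b"]),
            energies=EnergyDecomposition(
                e_dd=float(meta["e_dd"]), e_elastic=float(meta["e_elastic"]),
                e_bind=float(meta["e_bind"]), e_field=float(meta["e_field"])),
            positions=pos, moment_dirs=dirs,
            moment_mags=mmag, radii=radii, bound=bound))
        k += 2 + n
    return frames


def write_metadata(cfg: RunConfig, path, extra: Optional[dict] = None) -> None:
    """JSON sidecar sufficient to re-launch an identical run."""
    from . import __version__
    meta = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": int(cfg.seed),
        "version": __version__,
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
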